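species_group,chemical,log_kow,log_bcf_l5,log_k2,bcf_type
daphnia,synthetic-1,,3.059633579497368,-0.17700665255812753,kinetic
daphnia,synthetic-2,,3.0190227913553755,-0.3054745983434666,kinetic
daphnia,synthetic-3,,5.840343278453299,-2.4191310987582493,kinetic
daphnia,synthetic-4,,4.13291035568095,-1.1918479746302388,kinetic
daphnia,synthetic-5,,5.685160909383618,-2.210523408932497,kinetic
daphnia,synthetic-6,,5.95650450265393,-2.3664890925362396,kinetic
daphnia,synthetic-7,,5.184260110532048,-1.4997978405866321,kinetic
daphnia,synthetic-8,,3.3617469800862905,-0.4253102404286664,kinetic
daphnia,synthetic-9,,5.181104520125,-1.9796167124634354,kinetic
daphnia,synthetic-10,,3.043235924527357,0.00793515113643739,kinetic
daphnia,synthetic-11,,4.171882218624935,-0.8712304759843104,kinetic
daphnia,synthetic-12,,4.755078350081025,-1.6143162298381164,kinetic
daphnia,synthetic-13,,4.604915311758675,-1.3820018126646536,kinetic
daphnia,synthetic-14,,5.255117497116345,-1.4039349944359312,kinetic
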