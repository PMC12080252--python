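id,name,mw,sw_ug_per_L,log_kow,tm_K,pka
FAST,synthetic fast-eliminator demo chemical,220.0,50,5.5,450,
SLOW,synthetic slow-eliminator demo chemical,260.0,5,6.5,470,
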