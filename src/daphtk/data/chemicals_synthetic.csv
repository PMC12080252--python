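id,name,mw,sw_ug_per_L,log_kow,tm_K,pka
BCRB,7H-benzo[c]carbazole (synthetic property stand-in),217.27,80,5.2,431,
BNF,benzo[b]naphtho[1,2-d]furan (synthetic property stand-in),218.25,30,5.9,483,
BNT,benzo[b]naphtho[1,2-d]thiophene (synthetic property stand-in),234.32,15,6.0,460,
DNF,dinaphtho[2,1-b:1'2'-d]furan (synthetic property stand-in),268.31,2,6.9,453,
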