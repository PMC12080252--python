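chemical_id,conc_ug_per_L,replicate,offspring,parent_dead
FAST,0.0,1,69,False
FAST,0.0,2,71,False
FAST,0.0,3,68,False
FAST,0.0,4,76,False
FAST,0.0,5,70,False
FAST,0.0,6,88,False
FAST,0.0,7,67,False
FAST,0.0,8,67,False
FAST,0.0,9,65,False
FAST,0.0,10,78,False
FAST,0.5,1,70,False
FAST,0.5,2,70,False
FAST,0.5,3,79,False
FAST,0.5,4,60,False
FAST,0.5,5,70,False
FAST,0.5,6,84,False
FAST,0.5,7,66,False
FAST,0.5,8,70,False
FAST,0.5,9,70,False
FAST,0.5,10,78,False
FAST,1.0,1,60,False
FAST,1.0,2,63,False
FAST,1.0,3,53,False
FAST,1.0,4,55,False
FAST,1.0,5,64,False
FAST,1.0,6,69,False
FAST,1.0,7,66,False
FAST,1.0,8,62,False
FAST,1.0,9,65,False
FAST,1.0,10,69,False
FAST,2.5,1,50,False
FAST,2.5,2,48,False
FAST,2.5,3,56,False
FAST,2.5,4,55,False
FAST,2.5,5,58,False
FAST,2.5,6,47,False
FAST,2.5,7,54,False
FAST,2.5,8,52,False
FAST,2.5,9,57,False
FAST,2.5,10,50,False
FAST,5.0,1,39,False
FAST,5.0,2,35,False
FAST,5.0,3,36,False
FAST,5.0,4,38,False
FAST,5.0,5,33,False
FAST,5.0,6,33,False
FAST,5.0,7,43,False
FAST,5.0,8,37,False
FAST,5.0,9,41,False
FAST,5.0,10,43,False
FAST,10.0,1,21,False
FAST,10.0,2,24,False
FAST,10.0,3,22,False
FAST,10.0,4,21,False
FAST,10.0,5,24,False
FAST,10.0,6,24,False
FAST,10.0,7,21,False
FAST,10.0,8,21,False
FAST,10.0,9,23,False
FAST,10.0,10,25,False
FAST,25.0,1,10,False
FAST,25.0,2,10,False
FAST,25.0,3,8,False
FAST,25.0,4,9,False
FAST,25.0,5,11,False
FAST,25.0,6,8,False
FAST,25.0,7,12,False
FAST,25.0,8,9,False
FAST,25.0,9,9,False
FAST,25.0,10,9,False
SLOW,0.0,1,78,False
SLOW,0.0,2,70,False
SLOW,0.0,3,78,False
SLOW,0.0,4,82,False
SLOW,0.0,5,77,False
SLOW,0.0,6,74,False
SLOW,0.0,7,77,False
SLOW,0.0,8,86,False
SLOW,0.0,9,65,False
SLOW,0.0,10,88,False
SLOW,0.2,1,63,False
SLOW,0.2,2,73,False
SLOW,0.2,3,72,False
SLOW,0.2,4,76,False
SLOW,0.2,5,79,False
SLOW,0.2,6,56,False
SLOW,0.2,7,69,False
SLOW,0.2,8,69,False
SLOW,0.2,9,64,False
SLOW,0.2,10,58,False
SLOW,0.5,1,70,False
SLOW,0.5,2,61,False
SLOW,0.5,3,62,False
SLOW,0.5,4,80,False
SLOW,0.5,5,57,False
SLOW,0.5,6,58,False
SLOW,0.5,7,62,False
SLOW,0.5,8,63,False
SLOW,0.5,9,65,False
SLOW,0.5,10,64,False
SLOW,1.0,1,49,False
SLOW,1.0,2,51,False
SLOW,1.0,3,59,False
SLOW,1.0,4,42,False
SLOW,1.0,5,56,False
SLOW,1.0,6,56,False
SLOW,1.0,7,62,False
SLOW,1.0,8,51,False
SLOW,1.0,9,48,False
SLOW,1.0,10,46,False
SLOW,2.0,1,37,False
SLOW,2.0,2,34,False
SLOW,2.0,3,42,False
SLOW,2.0,4,36,False
SLOW,2.0,5,37,False
SLOW,2.0,6,37,False
SLOW,2.0,7,44,False
SLOW,2.0,8,42,False
SLOW,2.0,9,45,False
SLOW,2.0,10,37,False
SLOW,5.0,1,17,False
SLOW,5.0,2,17,False
SLOW,5.0,3,17,False
SLOW,5.0,4,19,False
SLOW,5.0,5,18,False
SLOW,5.0,6,18,False
SLOW,5.0,7,20,False
SLOW,5.0,8,18,False
SLOW,5.0,9,17,False
SLOW,5.0,10,21,False
SLOW,10.0,1,9,False
SLOW,10.0,2,8,False
SLOW,10.0,3,10,False
SLOW,10.0,4,9,False
SLOW,10.0,5,8,False
SLOW,10.0,6,11,False
SLOW,10.0,7,11,False
SLOW,10.0,8,10,False
SLOW,10.0,9,9,False
SLOW,10.0,10,12,False
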