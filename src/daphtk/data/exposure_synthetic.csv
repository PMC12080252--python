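chemical_id,level_id,cycle,stage,cw_ug_per_L
FAST,L1,1,initial,1.1296325509964162
FAST,L1,1,final,0.8781940147130225
FAST,L1,2,initial,1.037826673034051
FAST,L1,2,final,0.8458531397006531
FAST,L1,3,initial,0.9716084436391785
FAST,L1,3,final,0.9754831294987616
FAST,L1,4,initial,1.0620295043571317
FAST,L1,4,final,0.9323318609408636
FAST,L1,5,initial,1.064342155454538
FAST,L1,5,final,0.9056979421058046
FAST,L1,6,initial,0.9318275824255708
FAST,L1,6,final,0.8914258669352377
FAST,L2,1,initial,5.975927062377091
FAST,L2,1,final,3.8678403320674355
FAST,L2,2,initial,5.316024275613982
FAST,L2,2,final,4.189513411005849
FAST,L2,3,initial,4.9961817011824605
FAST,L2,3,final,5.072463184835074
FAST,L2,4,initial,5.551845928650488
FAST,L2,4,final,5.351129616784852
FAST,L2,5,initial,4.446542285207455
FAST,L2,5,final,5.174942473135053
FAST,L2,6,initial,5.503828273109965
FAST,L2,6,final,5.837096824571577
SLOW,L1,1,initial,0.4730238396238174
SLOW,L1,1,final,0.47229224718868656
SLOW,L1,2,initial,0.5121189401753196
SLOW,L1,2,final,0.4413563696668424
SLOW,L1,3,initial,0.5271881823435932
SLOW,L1,3,final,0.5656365115315038
SLOW,L1,4,initial,0.46991650855062345
SLOW,L1,4,final,0.5327626901119374
SLOW,L1,5,initial,0.5365375696827751
SLOW,L1,5,final,0.5691272564272435
SLOW,L1,6,initial,0.46745235357121356
SLOW,L1,6,final,0.4358884394788824
SLOW,L2,1,initial,4.130758420876953
SLOW,L2,1,final,5.207389920354418
SLOW,L2,2,initial,5.571976248216707
SLOW,L2,2,final,5.203703608100316
SLOW,L2,3,initial,5.490996838060028
SLOW,L2,3,final,4.587940724847509
SLOW,L2,4,initial,5.336699446174182
SLOW,L2,4,final,4.28366713988491
SLOW,L2,5,initial,4.61577690931657
SLOW,L2,5,final,3.9548980623782892
SLOW,L2,6,initial,5.1032028965062555
SLOW,L2,6,final,4.860924474269805
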