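chemical_id,phase,time_h,cd_ug_per_kg,replicate,wet_weight_mg
FAST,uptake,24.0,7697719.606028152,1,3.660059198962743
FAST,uptake,24.0,6393555.949132347,2,3.737850467570011
FAST,uptake,48.0,8935034.158191968,1,4.867693977831781
FAST,uptake,48.0,9884489.683674786,2,4.4181557503301585
FAST,uptake,72.0,10461528.379196312,1,3.7384524904890024
FAST,uptake,72.0,10430536.439723661,2,4.910058569568556
FAST,uptake,96.0,7364951.636406779,1,4.491817664695979
FAST,uptake,96.0,8962872.619951952,2,3.7048771711595707
FAST,uptake,120.0,9264662.206547318,1,5.138449706719351
FAST,uptake,120.0,12034944.947755903,2,4.514765129211433
FAST,depuration,24.0,842892.4566991453,1,6.273338261550949
FAST,depuration,24.0,970487.313543493,2,6.092687910271244
FAST,depuration,48.0,62816.19663091866,1,7.3886255666186145
FAST,depuration,48.0,83525.85594534127,2,8.394349565912838
FAST,depuration,72.0,8780.542710214635,1,6.064751710765248
FAST,depuration,72.0,7792.291391015693,2,6.254958639703821
FAST,depuration,96.0,541.5283062211162,1,7.76833870745531
FAST,depuration,96.0,666.5863566796872,2,10.620923564046402
SLOW,uptake,24.0,6529145.724670749,1,2.8449571648524565
SLOW,uptake,24.0,4469506.788657589,2,3.1504187079882096
SLOW,uptake,48.0,7123226.299666302,1,4.3005311484149225
SLOW,uptake,48.0,10593760.516902415,2,4.147892637760416
SLOW,uptake,72.0,13432645.873738024,1,3.4954532043726934
SLOW,uptake,72.0,9951102.366855193,2,4.4783663133625735
SLOW,uptake,96.0,13171004.831249246,1,5.193549976728229
SLOW,uptake,96.0,11070320.304590011,2,5.971935555474204
SLOW,uptake,120.0,12705708.971450264,1,5.6907185185405265
SLOW,uptake,120.0,14163152.310333073,2,5.812174658235104
SLOW,depuration,24.0,12606175.64269836,1,7.510252998777345
SLOW,depuration,24.0,11815183.824081184,2,5.401211769133905
SLOW,depuration,48.0,7934179.761269752,1,6.43332320212209
SLOW,depuration,48.0,9620324.444617018,2,6.321613503144526
SLOW,depuration,72.0,6651338.671990478,1,7.194021222167906
SLOW,depuration,72.0,7057900.888350331,2,8.465219119957633
SLOW,depuration,96.0,6479110.81800393,1,6.211367322213671
SLOW,depuration,96.0,4036658.27556408,2,9.774746752156087
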