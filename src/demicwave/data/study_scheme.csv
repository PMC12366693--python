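label,layer,x,y,n,mean_age
Bichon.HG.1,HG,764764.9,5243147.8,1,13700
Blatterhohle.HG.1,HG,830809,5718157,1,10602
Blatterhohle.HG.2,HG,830809,5718157,1,5719
Criewen.HG.1,HG,1582596,5901792,2,6635
LepenskiVir.HG.1,HG,2452472,4958554,2,9630
LepenskiVir.HG.2,HG,2452472,4958554,4,8750
LepenskiVir.HG.3,HG,2452472,4958554,3,8503
LepenskiVir.HG.4,HG,2452472,4958554,2,8069
Aktopraklik.FA.1,FA,3202638,4472220,4,8371
Aktopraklik.FA.2,FA,3202638,4472220,1,7534
AsparnSchletz.FA.1,FA,1833087,5407677,8,7497
AsparnSchletz.FA.2,FA,1833087,5407677,6,7189
Barcin.FA.1,FA,3295858,4487177,7,8227
Blatterhohle.FA.1,FA,830809,5718157,2,5819
Blatterhohle.FA.2,FA,830809,5718157,1,5416
Boncuklu.FA.1,FA,3658504,4202523,1,10078
Dillingen.FA.1,FA,1173118,5409760,1,7117
Essenbach.FA.1,FA,1360050,5411550,1,6975
Herxheim.FA.1,FA,914333.8,5470863.2,9,6959
LepenskiVir.FA.1,FA,2452011,4960008,4,7962
NeaNikomedeia.FA.1,FA,2477193,4517790,2,8141
PolgarFerenci.FA.1,FA,2354344,5326244,1,7139
StarcevoVinca.FA.1,FA,2299304,4986167,2,7527
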