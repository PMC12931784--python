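expert,criterion,l,m,u
TM1,S,0.241,0.268,0.347
TM1,O,0.122,0.122,0.14
TM1,D,0.587,0.587,0.648
TM2,S,0.581,0.581,0.627
TM2,O,0.212,0.237,0.299
TM2,D,0.155,0.164,0.19
TM3,S,0.161,0.161,0.193
TM3,O,0.516,0.516,0.597
TM3,D,0.26,0.288,0.4
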