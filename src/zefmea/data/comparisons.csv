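expert,best,worst,criterion,bo_term,ow_term
TM1,D,O,S,I,I
TM1,D,O,O,WI,EI
TM1,D,O,D,EI,FI
TM2,S,D,S,EI,AI
TM2,S,D,O,FI,WI
TM2,S,D,D,VI,EI
TM3,O,S,S,WI,EI
TM3,O,S,O,EI,I
TM3,O,S,D,I,VI
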