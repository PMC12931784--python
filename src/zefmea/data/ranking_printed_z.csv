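alternative,S_l,S_m,S_u,score,rank
A1,-0.18,-0.01,0.11,-0.03,17
A2,0.09,0.23,0.27,0.2,1
A3,-0.19,-0.12,0.11,-0.07,21
A4,-0.21,-0.03,0.11,-0.04,19
A5,-0.01,0.12,0.2,0.1,7
A6,0.04,0.17,0.24,0.15,4
A7,-0.15,-0.01,0.16,0.0,15
A8,-0.1,0.02,0.15,0.02,14
A9,0.05,0.17,0.27,0.16,3
A10,0.06,0.21,0.24,0.17,2
A11,-0.17,0.0,0.11,-0.02,16
A12,-0.31,-0.16,-0.03,-0.16,30
A13,-0.01,0.14,0.16,0.1,9
A14,-0.22,-0.05,0.09,-0.06,20
A15,-0.05,0.11,0.19,0.09,11
A16,-0.25,-0.11,0.09,-0.09,24
A17,0.02,0.09,0.23,0.12,6
A18,0.03,0.11,0.18,0.1,8
A19,-0.19,-0.07,0.14,-0.04,18
A20,-0.29,-0.13,0.03,-0.13,27
A21,-0.29,-0.13,0.03,-0.13,26
A22,-0.04,0.09,0.2,0.09,12
A23,-0.28,-0.13,-0.01,-0.14,29
A24,-0.24,-0.08,0.09,-0.08,23
A25,-0.08,0.03,0.21,0.05,13
A26,-0.25,-0.09,0.04,-0.1,25
A27,-0.29,-0.17,0.03,-0.14,28
A28,-0.19,-0.14,0.12,-0.07,22
A29,-0.04,0.11,0.21,0.1,10
A30,-0.01,0.12,0.24,0.12,5
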