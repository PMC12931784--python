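alternative,S_l,S_m,S_u,score,rank
A1,-0.72,-0.08,0.63,-0.06,18
A2,-0.23,0.35,0.93,0.35,1
A3,-0.82,-0.05,0.46,-0.14,25
A4,-0.69,-0.09,0.62,-0.05,17
A5,-0.38,0.18,0.81,0.2,6
A6,-0.31,0.26,0.86,0.27,4
A7,-0.6,0.01,0.67,0.03,14
A8,-0.7,0.05,0.66,0.0,15
A9,-0.3,0.31,0.89,0.3,2
A10,-0.26,0.26,0.89,0.3,3
A11,-0.77,-0.05,0.64,-0.06,19
A12,-0.91,-0.33,0.37,-0.29,30
A13,-0.59,0.13,0.74,0.09,13
A14,-0.76,-0.11,0.56,-0.11,21
A15,-0.5,0.13,0.8,0.15,10
A16,-0.71,-0.14,0.49,-0.12,22
A17,-0.52,0.25,0.78,0.17,8
A18,-0.46,0.18,0.72,0.15,9
A19,-0.67,-0.03,0.57,-0.04,16
A20,-0.88,-0.25,0.45,-0.23,27
A21,-0.86,-0.25,0.45,-0.22,26
A22,-0.57,0.15,0.76,0.11,11
A23,-0.86,-0.31,0.4,-0.26,29
A24,-0.8,-0.13,0.53,-0.13,24
A25,-0.55,0.12,0.73,0.1,12
A26,-0.65,-0.22,0.5,-0.13,23
A27,-0.89,-0.24,0.37,-0.25,28
A28,-0.69,-0.04,0.45,-0.1,20
A29,-0.46,0.18,0.81,0.17,7
A30,-0.42,0.22,0.85,0.22,5
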