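alternative,expert,Y,N,theta,n,R_printed
A1,TM1,8,2,2,12,0.6
A1,TM2,9,1,2,12,0.8
A1,TM3,8,2,2,12,0.6
A2,TM1,8,3,1,12,0.45
A2,TM2,8,3,1,12,0.45
A2,TM3,8,3,1,12,0.45
A3,TM1,6,5,1,12,0.09
A3,TM2,5,5,2,12,0.0
A3,TM3,6,5,1,12,0.09
A4,TM1,1,8,3,12,-0.78
A4,TM2,1,8,3,12,-0.78
A4,TM3,1,8,3,12,-0.78
A5,TM1,4,4,4,12,0.0
A5,TM2,4,4,4,12,0.0
A5,TM3,6,4,2,12,0.2
A6,TM1,3,6,3,12,-0.33
A6,TM2,3,6,3,12,-0.33
A6,TM3,3,6,3,12,-0.33
A7,TM1,6,4,2,12,0.2
A7,TM2,6,4,2,12,0.2
A7,TM3,6,5,1,12,0.09
A8,TM1,4,7,1,12,-0.27
A8,TM2,4,7,1,12,-0.27
A8,TM3,4,7,1,12,-0.27
A9,TM1,9,1,2,12,0.8
A9,TM2,8,1,3,12,0.78
A9,TM3,7,3,2,12,0.4
A10,TM1,6,4,2,12,0.2
A10,TM2,6,4,2,12,0.2
A10,TM3,6,4,2,12,0.2
A11,TM1,3,8,1,12,-0.45
A11,TM2,3,7,2,12,-0.4
A11,TM3,3,8,1,12,-0.45
A12,TM1,7,2,3,12,0.56
A12,TM2,7,2,3,12,0.56
A12,TM3,7,2,3,12,0.56
A13,TM1,5,5,2,12,0.0
A13,TM2,5,5,2,12,0.0
A13,TM3,5,5,2,12,0.0
A14,TM1,2,10,0,12,-0.67
A14,TM2,3,8,1,12,-0.45
A14,TM3,4,7,1,12,-0.27
A15,TM1,4,6,2,12,-0.2
A15,TM2,4,6,2,12,-0.2
A15,TM3,4,6,2,12,-0.2
A16,TM1,4,4,4,12,0.0
A16,TM2,4,4,4,12,0.0
A16,TM3,4,4,4,12,0.0
A17,TM1,6,2,4,12,0.5
A17,TM2,6,2,4,12,0.5
A17,TM3,6,2,4,12,0.5
A18,TM1,4,5,3,12,-0.11
A18,TM2,3,6,3,12,-0.33
A18,TM3,4,5,3,12,-0.11
A19,TM1,4,3,5,12,0.14
A19,TM2,4,3,5,12,0.14
A19,TM3,3,4,5,12,-0.14
A20,TM1,5,3,4,12,0.25
A20,TM2,5,3,4,12,0.25
A20,TM3,5,3,4,12,0.25
A21,TM1,5,6,1,12,-0.09
A21,TM2,5,6,1,12,-0.09
A21,TM3,5,6,1,12,-0.09
A22,TM1,3,8,1,12,-0.45
A22,TM2,2,9,1,12,-0.64
A22,TM3,3,8,1,12,-0.45
A23,TM1,9,2,1,12,0.64
A23,TM2,9,2,1,12,0.64
A23,TM3,7,4,1,12,0.27
A24,TM1,2,8,2,12,-0.6
A24,TM2,2,8,2,12,-0.6
A24,TM3,2,8,2,12,-0.6
A25,TM1,3,7,2,12,-0.4
A25,TM2,1,7,4,12,-0.75
A25,TM3,5,5,2,12,0.0
A26,TM1,7,4,1,12,0.27
A26,TM2,7,4,1,12,0.27
A26,TM3,7,4,1,12,0.27
A27,TM1,4,3,5,12,0.14
A27,TM2,4,3,5,12,0.14
A27,TM3,4,3,5,12,0.14
A28,TM1,2,10,0,12,-0.67
A28,TM2,4,1,7,12,0.6
A28,TM3,2,7,3,12,-0.56
A29,TM1,7,3,2,12,0.4
A29,TM2,7,3,2,12,0.4
A29,TM3,7,3,2,12,0.4
A30,TM1,4,5,3,12,-0.11
A30,TM2,5,4,1,12,-0.11
A30,TM3,4,5,3,12,-0.11
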