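alternative,criterion,l,m,u
A1,S,2.0,3.67,5.67
A1,O,3.67,5.67,7.67
A1,D,3.0,5.0,7.0
A2,S,5.67,7.67,9.33
A2,O,7.0,9.0,10.0
A2,D,7.67,9.0,9.67
A3,S,3.67,5.67,7.67
A3,O,1.67,3.67,5.67
A3,D,1.33,2.67,4.33
A4,S,1.67,3.67,5.67
A4,O,3.0,5.0,7.0
A4,D,3.67,5.67,7.67
A5,S,4.33,6.33,8.0
A5,O,5.67,7.67,9.33
A5,D,6.33,6.67,8.0
A6,S,5.0,7.0,8.67
A6,O,6.33,8.0,9.33
A6,D,7.0,8.33,9.0
A7,S,3.0,5.0,7.0
A7,O,3.0,5.0,7.0
A7,D,4.33,6.33,8.33
A8,S,4.0,5.67,7.33
A8,O,4.33,6.33,8.0
A8,D,2.33,4.33,6.33
A9,S,5.67,7.67,9.33
A9,O,5.67,7.67,9.33
A9,D,7.0,8.67,9.67
A10,S,4.33,6.33,8.33
A10,O,7.67,9.0,9.67
A10,D,7.67,9.0,9.67
A11,S,2.33,4.33,6.33
A11,O,4.33,6.33,8.33
A11,D,2.0,3.67,5.67
A12,S,0.33,1.33,3.0
A12,O,2.0,3.67,5.67
A12,D,1.33,2.67,4.33
A13,S,3.67,5.67,7.67
A13,O,7.67,9.33,10.0
A13,D,3.33,4.33,5.33
A14,S,1.67,3.67,5.67
A14,O,3.0,5.0,7.0
A14,D,2.67,4.33,6.0
A15,S,3.67,5.67,7.67
A15,O,5.67,7.67,9.33
A15,D,5.0,6.67,8.0
A16,S,1.67,3.67,5.67
A16,O,1.33,3.0,5.0
A16,D,3.67,5.67,7.33
A17,S,6.33,8.0,9.33
A17,O,5.0,7.0,8.67
A17,D,3.67,5.67,7.67
A18,S,5.33,6.67,7.67
A18,O,6.33,7.67,8.33
A18,D,4.67,5.67,7.33
A19,S,3.0,5.0,7.0
A19,O,1.67,3.67,5.67
A19,D,3.67,5.67,7.67
A20,S,0.67,2.33,4.33
A20,O,2.0,3.67,5.67
A20,D,1.67,3.67,5.67
A21,S,0.67,2.33,4.33
A21,O,2.0,3.67,5.67
A21,D,2.0,3.67,5.67
A22,S,4.33,6.33,8.33
A22,O,5.67,7.33,8.67
A22,D,3.67,5.67,7.67
A23,S,0.33,1.33,3.0
A23,O,2.67,4.0,5.67
A23,D,2.0,3.33,5.0
A24,S,1.67,3.67,5.67
A24,O,2.33,4.33,6.33
A24,D,2.33,4.33,6.33
A25,S,4.33,6.33,8.33
A25,O,3.67,5.67,7.67
A25,D,4.33,6.33,8.33
A26,S,1.0,2.0,3.67
A26,O,2.0,3.67,5.67
A26,D,4.67,6.0,7.33
A27,S,1.33,3.0,5.0
A27,O,1.33,3.0,5.0
A27,D,1.33,2.67,4.33
A28,S,3.67,5.67,7.67
A28,O,0.67,2.33,4.33
A28,D,3.33,4.67,6.0
A29,S,4.33,6.33,8.0
A29,O,5.0,7.0,8.67
A29,D,5.33,7.67,9.0
A30,S,5.0,7.0,8.67
A30,O,5.0,7.0,9.0
A30,D,5.67,7.67,9.33
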