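alternative,expert,criterion,rating_term,reliability_term
A1,TM1,S,M,M
A1,TM1,O,MH,VH
A1,TM1,D,MH,L
A1,TM2,S,MH,H
A1,TM2,O,VH,H
A1,TM2,D,VH,M
A1,TM3,S,MH,VH
A1,TM3,O,VH,H
A1,TM3,D,VH,H
A2,TM1,S,MH,H
A2,TM1,O,M,M
A2,TM1,D,M,L
A2,TM2,S,H,H
A2,TM2,O,MH,H
A2,TM2,D,MH,VH
A2,TM3,S,ML,L
A2,TM3,O,H,M
A2,TM3,D,H,H
A3,TM1,S,MH,L
A3,TM1,O,MH,H
A3,TM1,D,MH,H
A3,TM2,S,H,L
A3,TM2,O,MH,H
A3,TM2,D,H,L
A3,TM3,S,M,L
A3,TM3,O,MH,H
A3,TM3,D,MH,H
A4,TM1,S,M,VH
A4,TM1,O,M,M
A4,TM1,D,M,M
A4,TM2,S,ML,M
A4,TM2,O,M,L
A4,TM2,D,MH,M
A4,TM3,S,ML,M
A4,TM3,O,M,H
A4,TM3,D,M,ML
A5,TM1,S,MH,VH
A5,TM1,O,M,M
A5,TM1,D,ML,M
A5,TM2,S,L,VL
A5,TM2,O,M,M
A5,TM2,D,MH,M
A5,TM3,S,ML,M
A5,TM3,O,MH,L
A5,TM3,D,M,L
A6,TM1,S,MH,M
A6,TM1,O,H,H
A6,TM1,D,M,M
A6,TM2,S,MH,H
A6,TM2,O,MH,H
A6,TM2,D,M,M
A6,TM3,S,VH,M
A6,TM3,O,M,H
A6,TM3,D,MH,VH
A7,TM1,S,MH,L
A7,TM1,O,M,H
A7,TM1,D,MH,L
A7,TM2,S,ML,M
A7,TM2,O,MH,H
A7,TM2,D,MH,VH
A7,TM3,S,M,M
A7,TM3,O,ML,L
A7,TM3,D,M,L
A8,TM1,S,H,VH
A8,TM1,O,M,L
A8,TM1,D,ML,L
A8,TM2,S,L,VL
A8,TM2,O,M,M
A8,TM2,D,MH,H
A8,TM3,S,MH,M
A8,TM3,O,H,H
A8,TM3,D,ML,H
A9,TM1,S,L,M
A9,TM1,O,VH,VH
A9,TM1,D,L,VL
A9,TM2,S,VH,H
A9,TM2,O,VH,H
A9,TM2,D,MH,L
A9,TM3,S,H,H
A9,TM3,O,ML,M
A9,TM3,D,VH,M
A10,TM1,S,H,VH
A10,TM1,O,MH,M
A10,TM1,D,ML,M
A10,TM2,S,ML,H
A10,TM2,O,MH,L
A10,TM2,D,VH,H
A10,TM3,S,MH,VH
A10,TM3,O,H,M
A10,TM3,D,MH,M
A11,TM1,S,M,M
A11,TM1,O,MH,VH
A11,TM1,D,L,M
A11,TM2,S,M,M
A11,TM2,O,M,L
A11,TM2,D,M,VL
A11,TM3,S,ML,M
A11,TM3,O,MH,H
A11,TM3,D,M,VL
A12,TM1,S,ML,L
A12,TM1,O,M,VH
A12,TM1,D,VL,M
A12,TM2,S,L,L
A12,TM2,O,M,L
A12,TM2,D,ML,L
A12,TM3,S,VL,VL
A12,TM3,O,L,VH
A12,TM3,D,M,M
A13,TM1,S,M,L
A13,TM1,O,VH,M
A13,TM1,D,VL,L
A13,TM2,S,MH,H
A13,TM2,O,H,M
A13,TM2,D,ML,H
A13,TM3,S,M,L
A13,TM3,O,H,M
A13,TM3,D,VH,VH
A14,TM1,S,M,L
A14,TM1,O,ML,VL
A14,TM1,D,ML,H
A14,TM2,S,ML,M
A14,TM2,O,MH,L
A14,TM2,D,L,L
A14,TM3,S,ML,M
A14,TM3,O,M,L
A14,TM3,D,H,H
A15,TM1,S,MH,H
A15,TM1,O,MH,M
A15,TM1,D,ML,VH
A15,TM2,S,M,M
A15,TM2,O,H,M
A15,TM2,D,VH,H
A15,TM3,S,M,H
A15,TM3,O,MH,H
A15,TM3,D,MH,L
A16,TM1,S,ML,L
A16,TM1,O,M,VH
A16,TM1,D,ML,VL
A16,TM2,S,ML,M
A16,TM2,O,L,VL
A16,TM2,D,H,M
A16,TM3,S,M,L
A16,TM3,O,ML,L
A16,TM3,D,M,VH
A17,TM1,S,MH,L
A17,TM1,O,H,M
A17,TM1,D,MH,H
A17,TM2,S,H,H
A17,TM2,O,H,H
A17,TM2,D,VH,H
A17,TM3,S,MH,VH
A17,TM3,O,H,H
A17,TM3,D,VH,M
A18,TM1,S,H,VH
A18,TM1,O,MH,M
A18,TM1,D,VH,H
A18,TM2,S,MH,VH
A18,TM2,O,H,H
A18,TM2,D,MH,VH
A18,TM3,S,MH,L
A18,TM3,O,MH,VH
A18,TM3,D,H,H
A19,TM1,S,M,M
A19,TM1,O,ML,VL
A19,TM1,D,ML,VH
A19,TM2,S,MH,M
A19,TM2,O,M,M
A19,TM2,D,MH,L
A19,TM3,S,ML,L
A19,TM3,O,ML,VL
A19,TM3,D,MH,L
A20,TM1,S,ML,M
A20,TM1,O,MH,H
A20,TM1,D,ML,VH
A20,TM2,S,ML,M
A20,TM2,O,ML,M
A20,TM2,D,ML,M
A20,TM3,S,L,L
A20,TM3,O,L,MH
A20,TM3,D,M,M
A21,TM1,S,ML,VH
A21,TM1,O,ML,VH
A21,TM1,D,L,L
A21,TM2,S,L,VL
A21,TM2,O,MH,M
A21,TM2,D,ML,M
A21,TM3,S,ML,M
A21,TM3,O,L,VH
A21,TM3,D,MH,L
A22,TM1,S,M,M
A22,TM1,O,MH,H
A22,TM1,D,M,L
A22,TM2,S,MH,M
A22,TM2,O,VH,H
A22,TM2,D,VH,L
A22,TM3,S,H,H
A22,TM3,O,MH,M
A22,TM3,D,VH,M
A23,TM1,S,L,L
A23,TM1,O,MH,M
A23,TM1,D,VL,H
A23,TM2,S,ML,VL
A23,TM2,O,M,M
A23,TM2,D,ML,L
A23,TM3,S,VL,VL
A23,TM3,O,VL,VH
A23,TM3,D,MH,H
A24,TM1,S,M,VH
A24,TM1,O,M,M
A24,TM1,D,ML,M
A24,TM2,S,ML,M
A24,TM2,O,M,L
A24,TM2,D,M,M
A24,TM3,S,ML,VL
A24,TM3,O,ML,VH
A24,TM3,D,M,L
A25,TM1,S,MH,VH
A25,TM1,O,MH,H
A25,TM1,D,M,H
A25,TM2,S,MH,H
A25,TM2,O,M,VH
A25,TM2,D,MH,L
A25,TM3,S,M,H
A25,TM3,O,M,VH
A25,TM3,D,MH,H
A26,TM1,S,L,VH
A26,TM1,O,ML,L
A26,TM1,D,L,VL
A26,TM2,S,VL,VL
A26,TM2,O,MH,H
A26,TM2,D,VH,H
A26,TM3,S,M,VL
A26,TM3,O,L,VH
A26,TM3,D,MH,VH
A27,TM1,S,L,L
A27,TM1,O,M,H
A27,TM1,D,VL,VH
A27,TM2,S,M,M
A27,TM2,O,ML,L
A27,TM2,D,ML,M
A27,TM3,S,ML,M
A27,TM3,O,L,VL
A27,TM3,D,M,VL
A28,TM1,S,M,H
A28,TM1,O,L,VL
A28,TM1,D,L,L
A28,TM2,S,MH,VH
A28,TM2,O,ML,VL
A28,TM2,D,ML,VL
A28,TM3,S,M,VH
A28,TM3,O,ML,VH
A28,TM3,D,VH,M
A29,TM1,S,MH,H
A29,TM1,O,M,H
A29,TM1,D,ML,VH
A29,TM2,S,MH,H
A29,TM2,O,VH,H
A29,TM2,D,MH,M
A29,TM3,S,M,H
A29,TM3,O,MH,VH
A29,TM3,D,MH,M
A30,TM1,S,MH,M
A30,TM1,O,M,M
A30,TM1,D,VL,M
A30,TM2,S,ML,M
A30,TM2,O,ML,M
A30,TM2,D,ML,H
A30,TM3,S,MH,M
A30,TM3,O,ML,L
A30,TM3,D,M,VH
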