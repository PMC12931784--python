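alternative,criterion,l,m,u
A1,S,0.19,0.37,0.59
A1,O,0.32,0.54,0.75
A1,D,0.2,0.44,0.68
A2,S,0.59,0.81,1.0
A2,O,0.68,0.89,1.0
A2,D,0.76,0.92,1.0
A3,S,0.37,0.59,0.81
A3,O,0.11,0.32,0.54
A3,D,0.0,0.16,0.36
A4,S,0.15,0.37,0.59
A4,O,0.25,0.46,0.68
A4,D,0.28,0.52,0.76
A5,S,0.44,0.67,0.85
A5,O,0.54,0.75,0.93
A5,D,0.6,0.64,0.8
A6,S,0.52,0.74,0.93
A6,O,0.61,0.79,0.93
A6,D,0.68,0.84,0.92
A7,S,0.3,0.52,0.74
A7,O,0.25,0.46,0.68
A7,D,0.36,0.6,0.84
A8,S,0.41,0.59,0.78
A8,O,0.39,0.61,0.79
A8,D,0.12,0.36,0.6
A9,S,0.59,0.81,1.0
A9,O,0.54,0.75,0.93
A9,D,0.68,0.88,1.0
A10,S,0.44,0.67,0.89
A10,O,0.75,0.89,0.96
A10,D,0.76,0.92,1.0
A11,S,0.22,0.44,0.67
A11,O,0.39,0.61,0.82
A11,D,0.08,0.28,0.52
A12,S,0.0,0.11,0.3
A12,O,0.14,0.32,0.54
A12,D,0.0,0.16,0.36
A13,S,0.37,0.59,0.81
A13,O,0.75,0.93,1.0
A13,D,0.24,0.36,0.48
A14,S,0.15,0.37,0.59
A14,O,0.25,0.46,0.68
A14,D,0.16,0.36,0.56
A15,S,0.37,0.59,0.81
A15,O,0.54,0.75,0.93
A15,D,0.44,0.64,0.8
A16,S,0.15,0.37,0.59
A16,O,0.07,0.25,0.46
A16,D,0.28,0.52,0.72
A17,S,0.67,0.85,1.0
A17,O,0.46,0.68,0.86
A17,D,0.28,0.52,0.76
A18,S,0.56,0.7,0.81
A18,O,0.61,0.75,0.82
A18,D,0.4,0.52,0.72
A19,S,0.3,0.52,0.74
A19,O,0.11,0.32,0.54
A19,D,0.28,0.52,0.76
A20,S,0.04,0.22,0.44
A20,O,0.14,0.32,0.54
A20,D,0.04,0.28,0.52
A21,S,0.04,0.22,0.44
A21,O,0.14,0.32,0.54
A21,D,0.08,0.28,0.52
A22,S,0.44,0.67,0.89
A22,O,0.54,0.71,0.86
A22,D,0.28,0.52,0.76
A23,S,0.0,0.11,0.3
A23,O,0.21,0.36,0.54
A23,D,0.08,0.24,0.44
A24,S,0.15,0.37,0.59
A24,O,0.18,0.39,0.61
A24,D,0.12,0.36,0.6
A25,S,0.44,0.67,0.89
A25,O,0.32,0.54,0.75
A25,D,0.36,0.6,0.84
A26,S,0.07,0.19,0.37
A26,O,0.14,0.32,0.54
A26,D,0.4,0.56,0.72
A27,S,0.11,0.3,0.52
A27,O,0.07,0.25,0.46
A27,D,0.0,0.16,0.36
A28,S,0.37,0.59,0.81
A28,O,0.0,0.18,0.39
A28,D,0.24,0.4,0.56
A29,S,0.44,0.67,0.85
A29,O,0.46,0.68,0.86
A29,D,0.48,0.76,0.92
A30,S,0.52,0.74,0.93
A30,O,0.46,0.68,0.89
A30,D,0.52,0.76,0.96
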