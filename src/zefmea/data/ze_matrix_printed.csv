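alternative,expert,criterion,l,m,u
A1,TM1,S,3.59,4.49,5.39
A1,TM1,O,4.96,6.45,7.93
A1,TM1,D,4.3,5.59,6.88
A1,TM2,S,4.86,6.32,7.78
A1,TM2,O,7.78,8.76,9.73
A1,TM2,D,7.6,8.55,9.5
A1,TM3,S,4.96,6.45,7.93
A1,TM3,O,7.56,8.51,9.45
A1,TM3,D,7.56,8.51,9.45
A2,TM1,S,4.62,6.01,7.4
A2,TM1,O,3.43,4.29,5.15
A2,TM1,D,3.21,4.02,4.82
A2,TM2,S,6.47,7.4,8.32
A2,TM2,O,4.62,6.01,7.4
A2,TM2,D,4.94,6.43,7.91
A2,TM3,S,1.61,2.81,4.02
A2,TM3,O,6.01,6.86,7.72
A2,TM3,D,6.47,7.4,8.32
A3,TM1,S,3.2,4.16,5.12
A3,TM1,O,4.35,5.66,6.96
A3,TM1,D,4.35,5.66,6.96
A3,TM2,S,4.14,4.73,5.32
A3,TM2,O,4.28,5.57,6.85
A3,TM2,D,4.14,4.73,5.32
A3,TM3,S,2.56,3.2,3.84
A3,TM3,O,4.35,5.66,6.96
A3,TM3,D,4.9,6.38,7.85
A4,TM1,S,1.85,2.31,2.77
A4,TM1,O,1.36,1.69,2.03
A4,TM1,D,1.36,1.69,2.03
A4,TM2,S,0.68,1.19,1.69
A4,TM2,O,1.12,1.39,1.67
A4,TM2,D,1.69,2.2,2.71
A4,TM3,S,0.68,1.19,1.69
A4,TM3,O,1.61,2.02,2.42
A4,TM3,D,1.36,1.69,2.03
A5,TM1,S,4.89,6.36,7.83
A5,TM1,O,2.88,3.59,4.31
A5,TM1,D,1.44,2.52,3.59
A5,TM2,S,0.2,0.41,0.61
A5,TM2,O,2.88,3.59,4.31
A5,TM2,D,2.88,3.59,4.31
A5,TM3,S,1.57,2.74,3.92
A5,TM3,O,3.46,4.5,5.54
A5,TM3,D,2.77,3.46,4.16
A6,TM1,S,2.93,3.81,4.7
A6,TM1,O,4.89,5.59,6.29
A6,TM1,D,2.35,2.93,3.52
A6,TM2,S,3.5,4.54,5.59
A6,TM2,O,3.5,4.54,5.59
A6,TM2,D,2.35,2.93,3.52
A6,TM3,S,4.7,5.28,5.87
A6,TM3,O,2.8,3.5,4.2
A6,TM3,D,4.0,5.2,6.39
A7,TM1,S,3.46,4.5,5.54
A7,TM1,O,3.55,4.43,5.32
A7,TM1,D,3.46,4.5,5.54
A7,TM2,S,1.57,2.74,3.92
A7,TM2,O,4.43,5.77,7.1
A7,TM2,D,4.92,6.39,7.87
A7,TM3,S,2.99,3.74,4.49
A7,TM3,O,1.28,2.24,3.2
A7,TM3,D,1.28,2.24,3.2
A8,TM1,S,5.84,6.68,7.51
A8,TM1,O,2.02,2.52,3.03
A8,TM1,D,0.5,1.01,1.51
A8,TM2,S,0.17,0.35,0.52
A8,TM2,O,2.45,3.06,3.68
A8,TM2,D,3.65,4.75,5.84
A8,TM3,S,3.06,3.98,4.9
A8,TM3,O,5.11,5.84,6.57
A8,TM3,D,1.46,2.56,3.65
A9,TM1,S,0.95,1.9,2.85
A9,TM1,O,7.97,8.96,9.96
A9,TM1,D,0.97,1.95,2.92
A9,TM2,S,7.76,8.73,9.7
A9,TM2,O,7.76,8.73,9.7
A9,TM2,D,4.62,6.01,7.4
A9,TM3,S,6.42,7.33,8.25
A9,TM3,O,1.69,2.95,4.21
A9,TM3,D,5.9,6.74,7.58
A10,TM1,S,6.88,7.87,8.85
A10,TM1,O,3.92,5.09,6.27
A10,TM1,D,1.57,2.74,3.92
A10,TM2,S,1.77,3.1,4.43
A10,TM2,O,4.85,5.54,6.24
A10,TM2,D,7.1,7.98,8.87
A10,TM3,S,4.92,6.39,7.87
A10,TM3,O,5.48,6.27,7.05
A10,TM3,D,3.92,5.09,6.27
A11,TM1,S,2.12,2.65,3.19
A11,TM1,O,3.61,4.7,5.78
A11,TM1,D,0.53,1.06,1.59
A11,TM2,S,2.23,2.78,3.34
A11,TM2,O,1.83,2.29,2.75
A11,TM2,D,0.63,0.79,0.95
A11,TM3,S,1.06,1.86,2.65
A11,TM3,O,3.16,4.11,5.06
A11,TM3,D,0.6,0.75,0.9
A12,TM1,S,1.69,2.95,4.22
A12,TM1,O,3.96,4.95,5.94
A12,TM1,D,0.0,0.89,1.77
A12,TM2,S,0.84,1.69,2.53
A12,TM2,O,3.37,4.22,5.06
A12,TM2,D,1.69,2.95,4.22
A12,TM3,S,0.0,0.76,1.52
A12,TM3,O,0.99,1.98,2.97
A12,TM3,D,3.54,4.43,5.32
A13,TM1,S,1.18,2.07,2.96
A13,TM1,O,5.75,6.47,7.19
A13,TM1,D,0.59,1.18,1.77
A13,TM2,S,4.28,5.57,6.85
A13,TM2,O,5.03,5.75,6.47
A13,TM2,D,1.71,3.0,4.28
A13,TM3,S,2.37,2.96,3.55
A13,TM3,O,5.03,5.75,6.47
A13,TM3,D,7.83,8.81,9.79
A14,TM1,S,1.37,1.71,2.05
A14,TM1,O,0.24,0.41,0.59
A14,TM1,D,0.99,1.73,2.47
A14,TM2,S,1.06,1.86,2.65
A14,TM2,O,2.18,2.84,3.5
A14,TM2,D,0.44,0.87,1.31
A14,TM3,S,1.23,2.15,3.06
A14,TM3,O,2.02,2.52,3.03
A14,TM3,D,5.11,5.84,6.57
A15,TM1,S,3.83,4.98,6.13
A15,TM1,O,3.21,4.18,5.14
A15,TM1,D,1.75,3.06,4.38
A15,TM2,S,2.57,3.21,3.86
A15,TM2,O,4.5,5.14,5.79
A15,TM2,D,6.13,6.89,7.66
A15,TM3,S,3.06,3.83,4.6
A15,TM3,O,3.83,4.98,6.13
A15,TM3,D,2.65,3.44,4.23
A16,TM1,S,1.18,2.07,2.96
A16,TM1,O,3.92,4.89,5.87
A16,TM1,D,0.41,0.71,1.02
A16,TM2,S,1.44,2.52,3.59
A16,TM2,O,0.2,0.41,0.61
A16,TM2,D,5.03,5.75,6.47
A16,TM3,S,2.37,2.96,3.55
A16,TM3,O,1.18,2.07,2.96
A16,TM3,D,3.92,4.89,5.87
A17,TM1,S,4.11,5.34,6.57
A17,TM1,O,6.1,6.97,7.84
A17,TM1,D,4.65,6.05,7.45
A17,TM2,S,6.52,7.45,8.38
A17,TM2,O,6.52,7.45,8.38
A17,TM2,D,7.45,8.38,9.31
A17,TM3,S,4.95,6.43,7.92
A17,TM3,O,6.52,7.45,8.38
A17,TM3,D,6.97,7.84,8.71
A18,TM1,S,6.46,7.38,8.31
A18,TM1,O,3.39,4.4,5.42
A18,TM1,D,6.46,7.27,8.07
A18,TM2,S,4.0,5.2,6.39
A18,TM2,O,4.89,5.59,6.29
A18,TM2,D,4.0,5.2,6.39
A18,TM3,S,2.79,3.63,4.46
A18,TM3,O,4.61,6.0,7.38
A18,TM3,D,5.65,6.46,7.27
A19,TM1,S,3.06,3.83,4.59
A19,TM1,O,0.85,1.48,2.11
A19,TM1,D,1.96,3.44,4.91
A19,TM2,S,3.83,4.97,6.12
A19,TM2,O,3.06,3.83,4.59
A19,TM2,D,3.33,4.33,5.32
A19,TM3,S,1.1,1.92,2.74
A19,TM3,O,0.38,0.66,0.94
A19,TM3,D,2.74,3.56,4.38
A20,TM1,S,1.6,2.79,3.99
A20,TM1,O,4.47,5.81,7.16
A20,TM1,D,1.97,3.44,4.92
A20,TM2,S,1.6,2.79,3.99
A20,TM2,O,1.6,2.79,3.99
A20,TM2,D,1.6,2.79,3.99
A20,TM3,S,0.72,1.43,2.15
A20,TM3,O,0.8,1.6,2.4
A20,TM3,D,3.19,3.99,4.79
A21,TM1,S,1.87,3.27,4.67
A21,TM1,O,1.87,3.27,4.67
A21,TM1,D,0.56,1.13,1.69
A21,TM2,S,0.19,0.39,0.58
A21,TM2,O,3.43,4.45,5.48
A21,TM2,D,1.37,2.4,3.43
A21,TM3,S,1.37,2.4,3.43
A21,TM3,O,0.82,1.63,2.45
A21,TM3,D,2.82,3.67,4.51
A22,TM1,S,2.12,2.65,3.19
A22,TM1,O,3.16,4.11,5.06
A22,TM1,D,1.75,2.18,2.62
A22,TM2,S,2.17,2.82,3.47
A22,TM2,O,4.13,4.65,5.16
A22,TM2,D,2.85,3.21,3.57
A22,TM3,S,4.43,5.06,5.69
A22,TM3,O,2.65,3.45,4.25
A22,TM3,D,4.25,4.78,5.31
A23,TM1,S,0.87,1.75,2.62
A23,TM1,O,4.54,5.9,7.26
A23,TM1,D,0.0,0.95,1.9
A23,TM2,S,1.61,2.83,4.04
A23,TM2,O,3.63,4.54,5.45
A23,TM2,D,1.75,3.06,4.37
A23,TM3,S,0.0,0.55,1.1
A23,TM3,O,0.0,0.98,1.97
A23,TM3,D,4.49,5.84,7.18
A24,TM1,S,2.48,3.1,3.71
A24,TM1,O,1.82,2.27,2.73
A24,TM1,D,0.91,1.59,2.27
A24,TM2,S,0.91,1.59,2.27
A24,TM2,O,1.5,1.87,2.24
A24,TM2,D,1.82,2.27,2.73
A24,TM3,S,0.26,0.45,0.65
A24,TM3,O,1.24,2.17,3.1
A24,TM3,D,1.5,1.87,2.24
A25,TM1,S,3.79,4.93,6.07
A25,TM1,O,3.32,4.31,5.31
A25,TM1,D,2.65,3.32,3.98
A25,TM2,S,2.14,2.78,3.43
A25,TM2,O,1.96,2.45,2.94
A25,TM2,D,1.48,1.92,2.37
A25,TM3,S,3.43,4.28,5.14
A25,TM3,O,3.92,4.89,5.87
A25,TM3,D,4.28,5.57,6.85
A26,TM1,S,0.98,1.97,2.95
A26,TM1,O,1.45,2.54,3.63
A26,TM1,D,0.55,1.1,1.65
A26,TM2,S,0.0,0.55,1.1
A26,TM2,O,4.49,5.84,7.18
A26,TM2,D,7.18,8.08,8.98
A26,TM3,S,2.2,2.75,3.3
A26,TM3,O,0.98,1.97,2.95
A26,TM3,D,4.92,6.4,7.88
A27,TM1,S,0.67,1.33,2.0
A27,TM1,O,3.51,4.39,5.27
A27,TM1,D,0.0,0.98,1.96
A27,TM2,S,3.06,3.83,4.59
A27,TM2,O,1.33,2.33,3.33
A27,TM2,D,1.53,2.68,3.83
A27,TM3,S,1.53,2.68,3.83
A27,TM3,O,0.42,0.85,1.27
A27,TM3,D,1.69,2.11,2.54
A28,TM1,S,1.98,2.47,2.97
A28,TM1,O,0.12,0.24,0.35
A28,TM1,D,0.34,0.68,1.02
A28,TM2,S,4.96,6.45,7.93
A28,TM2,O,1.72,3.01,4.3
A28,TM2,D,1.57,2.75,3.93
A28,TM3,S,2.61,3.26,3.92
A28,TM3,O,1.14,2.0,2.85
A28,TM3,D,3.83,4.31,4.79
A29,TM1,S,4.58,5.96,7.33
A29,TM1,O,3.67,4.58,5.5
A29,TM1,D,1.97,3.46,4.94
A29,TM2,S,4.58,5.96,7.33
A29,TM2,O,7.33,8.25,9.17
A29,TM2,D,4.21,5.48,6.74
A29,TM3,S,3.67,4.58,5.5
A29,TM3,O,4.94,6.42,7.9
A29,TM3,D,4.21,5.48,6.74
A30,TM1,S,3.39,4.4,5.42
A30,TM1,O,2.71,3.39,4.07
A30,TM1,D,0.0,0.68,1.36
A30,TM2,S,1.36,2.37,3.39
A30,TM2,O,1.36,2.37,3.39
A30,TM2,D,1.61,2.83,4.04
A30,TM3,S,3.39,4.4,5.42
A30,TM3,O,1.12,1.95,2.79
A30,TM3,D,3.69,4.61,5.54
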