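weight,S1,S2,S3,S4,S5,S6,S7
70,0.72,1.05,0.74,1.12,0.81,0.86,0.99
90,0.93,1.36,0.94,1.44,1.04,1.11,1.27
110,1.14,1.66,1.16,1.76,1.27,1.35,1.55
130,1.35,1.96,1.36,2.08,1.05,1.59,1.82
150,1.55,2.27,1.58,2.40,1.73,1.85,2.15
170,1.76,2.57,1.78,2.72,2.00,2.09,2.40
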