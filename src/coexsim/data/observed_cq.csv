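receptor,rt,ANTa,ANTb,ANTc,Ba,Bb,Bc,Ma,Mb,Mc,La,Lb,Lc,Genomic
TKr,RT,0,34.1,34.5,31.36,35.35,29.63,38.51,32.18,34.03,39,0,37.59,24.09
TKr,RT-,0,0,0,0,0,0,0,0,0,0,0,0,0
Mas-ATr,RT,35.72,33.65,33.41,32.28,37.32,31.26,39.8,32.42,33.55,35.77,37.6,36.29,30.24
Mas-ATr,RT-,0,0,0,0,0,0,0,0,0,0,0,0,39.48
FMRFr,RT,32.43,29.04,29.1,26.56,31.14,25.95,33.01,27.53,28.03,31.57,32.22,30.89,24.85
FMRFr,RT-,0,0,0,0,0,0,0,0,0,0,0,0,0
MIPr,RT,33.91,31.03,30.69,29.55,33.31,27.94,34.94,28.92,30.15,34.97,35.73,33.12,23.86
MIPr,RT-,0,0,0,0,0,0,0,0,0,0,0,0,0
AST-Ar,RT,37.28,32.23,31.23,29.26,23.63,28.17,37.39,31.19,32.39,35.43,37.35,35.14,25.61
AST-Ar,RT-,0,0,0,0,0,0,0,0,0,0,0,0,0
GABA-B,RT,32.21,29.09,28.62,27.91,31.17,25.97,33.48,27.26,28.51,33.26,35.51,31.97,23.72
GABA-B,RT-,0,0,0,0,0,0,0,0,0,0,0,0,0
vGlut,RT,x,x,x,24.43,28.40,23.21,x,x,x,32.60,0,31.96,24.82
vGlut,RT-,x,x,x,0,0,0,x,x,x,0,0,0,0
RpS3,RT,25.61,22.49,22.16,22.91,26.65,21.41,28.89,23.16,24.04,28.93,28.6,26.04,24.18
RpS3,RT-,0,0,0,0,0,0,0,0,0,0,0,0,0
RpS3-52C,RT,24.54,21.85,21.87,23.18,27.04,21.31,28,23.21,24.18,26.68,28.03,25.23,18.29
RpS3-52C,RT-,4.41,0,0,39,37.27,0,37.2,5.13,28.94,36.16,38.98,0,5.23
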