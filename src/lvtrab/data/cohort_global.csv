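patient_id,global_fd,tm_pct
P1,1.37,38.51
P2,1.31,31.43
P3,1.28,32.29
P4,1.21,31.51
P5,1.33,44.72
P6,1.30,40.73
P7,1.23,37.28
P8,1.39,31.02
P9,1.28,27.40
P10,1.34,28.99
P11,1.26,28.62
P12,1.31,34.31
P13,1.20,37.34
P14,1.27,47.35
P15,1.21,33.98
P16,1.37,34.71
P17,1.27,30.94
P18,1.27,30.15
P19,1.34,31.73
P20,1.24,28.78
P21,1.31,34.06
P22,1.32,36.30
P23,1.27,29.04
P24,1.38,32.20
P25,1.30,29.14
P26,1.33,36.33
P27,1.18,32.10
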