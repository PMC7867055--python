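patient_id,slice_id,fd,tm_pct
P4,B1,1.08,19.15
P4,B2,1.17,31.14
P4,B3,1.32,36.11
P4,M1,1.27,30.39
P4,A1,1.21,40.69
P4,A2,1.31,29.88
P4,A3,1.11,29.96
P7,B1,1.10,28.61
P7,B2,1.14,21.14
P7,B3,1.20,39.59
P7,M1,1.20,44.45
P7,M2,1.13,44.60
P7,M3,1.19,38.53
P7,A1,1.31,32.41
P7,A2,1.27,48.67
P7,A3,1.44,34.36
P13,B1,1.13,0.81
P13,B2,1.21,24.77
P13,B3,1.35,33.29
P13,M1,1.27,44.75
P13,M2,1.28,46.19
P13,M3,1.31,49.17
P13,A1,1.24,51.89
P13,A2,1.06,43.59
P13,A3,1.11,30.38
P15,B1,1.22,48.14
P15,B2,1.26,43.79
P15,B3,1.23,37.44
P15,M1,1.18,35.61
P15,M3,1.18,25.12
P15,A1,1.21,31.16
P15,A2,1.17,45.73
P15,A3,1.27,30.33
P20,B1,1.17,35.44
P20,B2,1.23,36.20
P20,B3,1.20,31.02
P20,M1,1.33,41.35
P20,M3,1.33,34.06
P20,A1,1.21,25.64
P20,A2,1.20,18.21
P20,A3,1.22,18.87
P27,B1,1.19,33.83
P27,B2,1.17,36.73
P27,B3,1.17,34.61
P27,A1,1.18,26.01
P27,A2,1.25,22.46
P27,A3,1.14,35.93
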