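condition,class,mean_pct,sd_pct
1-1,BASELINE,100.00,0.00
1-1,0VLA,90.07,0.39
1-1,PVHA,89.56,0.58
1-1,NVHA,89.49,0.36
1-1,PVLA,89.41,0.38
1-1,NVLA,89.49,0.36
1-10-f,BASELINE,100.00,0.00
1-10-f,0VLA,87.65,1.24
1-10-f,PVHA,87.06,1.16
1-10-f,NVHA,86.25,1.20
1-10-f,PVLA,87.28,0.92
1-10-f,NVLA,86.62,1.19
1-10-l,BASELINE,100.00,0.00
1-10-l,0VLA,86.76,1.73
1-10-l,PVHA,87.94,1.21
1-10-l,NVHA,86.40,1.05
1-10-l,PVLA,87.06,1.21
1-10-l,NVLA,86.91,1.09
1-2,BASELINE,100.00,0.00
1-2,0VLA,90.59,0.31
1-2,PVHA,90.59,0.47
1-2,NVHA,90.00,0.62
1-2,PVLA,89.71,0.00
1-2,NVLA,89.85,0.31
2-10-f,BASELINE,100.00,0.00
2-10-f,0VLA,86.25,1.20
2-10-f,PVHA,87.94,0.93
2-10-f,NVHA,85.44,1.38
2-10-f,PVLA,87.43,1.12
2-10-f,NVLA,86.47,1.11
2-10-l,BASELINE,100.00,0.00
2-10-l,0VLA,87.43,0.88
2-10-l,PVHA,87.50,1.20
2-10-l,NVHA,85.81,1.04
2-10-l,PVLA,87.43,1.07
2-10-l,NVLA,86.91,1.62
2-2,BASELINE,99.97,0.06
2-2,0VLA,81.18,0.71
2-2,PVHA,84.04,1.04
2-2,NVHA,81.32,1.11
2-2,PVLA,82.57,1.15
2-2,NVLA,79.41,0.98
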