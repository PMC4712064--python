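condition,class,mean_pct,sd_pct
1-1,BASELINE,100.00,0.00
1-1,0VLA,88.88,0.40
1-1,PVHA,90.00,0.00
1-1,NVHA,90.00,0.00
1-1,PVLA,90.00,0.00
1-1,NVLA,88.75,0.00
1-10-f,BASELINE,100.00,0.00
1-10-f,0VLA,89.38,1.06
1-10-f,PVHA,88.00,1.05
1-10-f,NVHA,89.88,0.71
1-10-f,PVLA,89.38,0.66
1-10-f,NVLA,90.00,0.59
1-10-l,BASELINE,100.00,0.00
1-10-l,0VLA,89.00,0.79
1-10-l,PVHA,88.00,0.65
1-10-l,NVHA,90.13,0.40
1-10-l,PVLA,89.38,1.06
1-10-l,NVLA,90.25,1.29
1-2,BASELINE,100.00,0.00
1-2,0VLA,90.00,0.00
1-2,PVHA,90.00,0.00
1-2,NVHA,90.38,0.60
1-2,PVLA,89.88,0.40
1-2,NVLA,89.00,0.53
2-10-f,BASELINE,100.00,0.00
2-10-f,0VLA,88.88,0.71
2-10-f,PVHA,88.38,1.03
2-10-f,NVHA,90.13,0.92
2-10-f,PVLA,89.50,0.87
2-10-f,NVLA,90.00,0.83
2-10-l,BASELINE,100.00,0.00
2-10-l,0VLA,89.13,1.03
2-10-l,PVHA,88.75,0.83
2-10-l,NVHA,90.00,0.59
2-10-l,PVLA,89.38,0.66
2-10-l,NVLA,89.88,1.09
2-2,BASELINE,100.00,0.00
2-2,0VLA,87.63,0.40
2-2,PVHA,87.25,0.99
2-2,NVHA,85.00,1.32
2-2,PVLA,85.50,1.05
2-2,NVLA,87.38,0.92
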