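condition,class,mean_pct,sd_pct
1-1,BASELINE,100.00,0.00
1-1,0VLA,90.00,0.00
1-1,PVHA,90.00,0.00
1-1,NVHA,90.00,0.00
1-1,PVLA,90.00,0.00
1-1,NVLA,90.00,0.00
1-10-f,BASELINE,100.00,0.00
1-10-f,0VLA,89.63,0.84
1-10-f,PVHA,89.75,0.53
1-10-f,NVHA,88.50,0.79
1-10-f,PVLA,90.13,0.40
1-10-f,NVLA,89.88,0.71
1-10-l,BASELINE,100.00,0.00
1-10-l,0VLA,90.25,0.79
1-10-l,PVHA,89.88,0.40
1-10-l,NVHA,89.00,0.79
1-10-l,PVLA,90.00,0.83
1-10-l,NVLA,90.13,0.71
1-2,BASELINE,100.00,0.00
1-2,0VLA,90.00,0.00
1-2,PVHA,90.00,0.00
1-2,NVHA,90.13,0.40
1-2,PVLA,90.00,0.00
1-2,NVLA,90.00,0.00
2-10-f,BASELINE,100.00,0.00
2-10-f,0VLA,90.00,0.59
2-10-f,PVHA,89.50,0.65
2-10-f,NVHA,89.13,0.60
2-10-f,PVLA,89.88,0.71
2-10-f,NVLA,89.88,1.38
2-10-l,BASELINE,100.00,0.00
2-10-l,0VLA,90.13,0.92
2-10-l,PVHA,89.38,0.88
2-10-l,NVHA,88.75,0.00
2-10-l,PVLA,89.38,1.35
2-10-l,NVLA,90.00,1.02
2-2,BASELINE,100.00,0.00
2-2,0VLA,89.00,1.15
2-2,PVHA,88.63,0.71
2-2,NVHA,87.88,0.84
2-2,PVLA,88.88,0.92
2-2,NVLA,86.25,1.02
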