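condition,class,mean_pct,sd_pct
1-1,BASELINE,100.00,0.00
1-1,0VLA,88.47,0.60
1-1,PVHA,88.38,0.63
1-1,NVHA,87.31,0.54
1-1,PVLA,88.47,0.41
1-1,NVLA,87.04,0.49
1-10-f,BASELINE,100.00,0.00
1-10-f,0VLA,88.75,0.73
1-10-f,PVHA,86.02,0.87
1-10-f,NVHA,84.95,0.82
1-10-f,PVLA,84.81,0.81
1-10-f,NVLA,86.90,0.90
1-10-l,BASELINE,100.00,0.00
1-10-l,0VLA,88.75,0.82
1-10-l,PVHA,86.20,0.65
1-10-l,NVHA,84.58,1.18
1-10-l,PVLA,85.28,1.11
1-10-l,NVLA,87.36,0.76
1-2,BASELINE,100.00,0.00
1-2,0VLA,90.65,0.48
1-2,PVHA,89.44,0.65
1-2,NVHA,87.92,0.63
1-2,PVLA,89.72,0.68
1-2,NVLA,89.95,0.62
2-2,BASELINE,100.00,0.00
2-2,0VLA,75.69,1.47
2-2,PVHA,77.13,0.98
2-2,NVHA,80.69,0.58
2-2,PVLA,79.72,0.89
2-2,NVLA,76.57,1.00
2-10-f,BASELINE,100.00,0.00
2-10-f,0VLA,89.07,1.03
2-10-f,PVHA,85.88,1.05
2-10-f,NVHA,85.19,0.87
2-10-f,PVLA,85.46,1.10
2-10-f,NVLA,87.27,0.91
2-10-l,BASELINE,100.00,0.00
2-10-l,0VLA,88.47,0.91
2-10-l,PVHA,86.81,0.82
2-10-l,NVHA,85.05,0.66
2-10-l,PVLA,85.37,0.73
2-10-l,NVLA,87.45,1.49
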