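condition,class,mean_pct,sd_pct
1-1,BASELINE,100.00,0.00
1-1,0VLA,88.60,0.39
1-1,PVHA,87.87,0.79
1-1,NVHA,88.82,0.47
1-1,PVLA,88.01,0.70
1-1,NVLA,87.13,0.62
1-10-f,BASELINE,100.00,0.00
1-10-f,0VLA,88.75,1.73
1-10-f,PVHA,85.96,1.32
1-10-f,NVHA,83.82,0.78
1-10-f,PVLA,84.78,1.04
1-10-f,NVLA,85.96,1.45
1-10-l,BASELINE,100.00,0.00
1-10-l,0VLA,88.75,0.98
1-10-l,PVHA,86.69,1.17
1-10-l,NVHA,84.41,1.54
1-10-l,PVLA,85.96,1.68
1-10-l,NVLA,85.81,1.63
1-2,BASELINE,100.00,0.00
1-2,0VLA,90.74,0.71
1-2,PVHA,89.19,0.36
1-2,NVHA,88.46,0.36
1-2,PVLA,89.63,0.54
1-2,NVLA,90.00,0.38
2-10-f,BASELINE,100.00,0.00
2-10-f,0VLA,89.04,0.64
2-10-f,PVHA,86.62,1.38
2-10-f,NVHA,84.26,0.86
2-10-f,PVLA,86.32,0.86
2-10-f,NVLA,86.47,1.05
2-10-l,BASELINE,100.00,0.00
2-10-l,0VLA,88.97,0.60
2-10-l,PVHA,86.69,1.36
2-10-l,NVHA,83.75,1.12
2-10-l,PVLA,85.22,1.36
2-10-l,NVLA,86.10,1.32
2-2,BASELINE,99.99,0.05
2-2,0VLA,77.65,1.21
2-2,PVHA,78.31,1.05
2-2,NVHA,81.76,0.90
2-2,PVLA,77.06,1.62
2-2,NVLA,78.46,1.55
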