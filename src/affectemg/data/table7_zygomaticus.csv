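condition,class,mean_pct,sd_pct
1-1,BASELINE,99.95,0.09
1-1,0VLA,19.68,0.88
1-1,PVHA,17.55,1.41
1-1,NVHA,19.31,1.38
1-1,PVLA,20.65,1.59
1-1,NVLA,19.17,1.35
1-10-f,BASELINE,100.00,0.00
1-10-f,0VLA,54.81,3.63
1-10-f,PVHA,52.69,1.59
1-10-f,NVHA,55.93,3.24
1-10-f,PVLA,52.50,1.35
1-10-f,NVLA,61.67,4.05
1-10-l,BASELINE,100.00,0.00
1-10-l,0VLA,54.58,1.83
1-10-l,PVHA,52.96,2.12
1-10-l,NVHA,56.44,3.21
1-10-l,PVLA,50.65,1.79
1-10-l,NVLA,62.92,3.43
1-2,BASELINE,100.00,0.00
1-2,0VLA,60.00,2.18
1-2,PVHA,54.81,1.97
1-2,NVHA,57.36,3.14
1-2,PVLA,54.81,2.12
1-2,NVLA,65.93,2.50
2-10-f,BASELINE,100.00,0.00
2-10-f,0VLA,54.40,3.10
2-10-f,PVHA,52.87,1.41
2-10-f,NVHA,56.34,2.13
2-10-f,PVLA,51.20,1.29
2-10-f,NVLA,63.01,3.00
2-10-l,BASELINE,100.00,0.00
2-10-l,0VLA,54.44,1.59
2-10-l,PVHA,52.45,0.90
2-10-l,NVHA,55.79,3.08
2-10-l,PVLA,51.30,1.32
2-10-l,NVLA,64.58,3.64
2-2,BASELINE,99.94,0.09
2-2,0VLA,13.19,2.35
2-2,PVHA,18.24,1.18
2-2,NVHA,20.93,0.72
2-2,PVLA,17.59,1.43
2-2,NVLA,18.61,1.56
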