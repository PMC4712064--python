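condition,class,mean_pct,sd_pct
1-1,BASELINE,99.87,0.10
1-1,0VLA,22.22,1.43
1-1,PVHA,34.07,1.97
1-1,NVHA,38.94,1.84
1-1,PVLA,34.68,1.60
1-1,NVLA,30.83,2.27
1-10-f,BASELINE,100.00,0.00
1-10-f,0VLA,55.23,2.58
1-10-f,PVHA,61.20,3.04
1-10-f,NVHA,56.34,2.70
1-10-f,PVLA,60.19,2.43
1-10-f,NVLA,62.87,2.50
1-10-l,BASELINE,100.00,0.00
1-10-l,0VLA,56.53,3.58
1-10-l,PVHA,62.18,1.50
1-10-l,NVHA,56.81,2.40
1-10-l,PVLA,60.14,1.41
1-10-l,NVLA,61.85,2.78
1-2,BASELINE,100.00,0.00
1-2,0VLA,68.10,2.74
1-2,PVHA,69.86,1.55
1-2,NVHA,65.42,1.73
1-2,PVLA,63.89,2.82
1-2,NVLA,65.88,3.18
2-10-f,BASELINE,100.00,0.00
2-10-f,0VLA,55.83,3.17
2-10-f,PVHA,61.67,2.44
2-10-f,NVHA,56.71,2.19
2-10-f,PVLA,59.12,3.13
2-10-f,NVLA,61.90,3.19
2-10-l,BASELINE,100.00,0.00
2-10-l,0VLA,55.60,3.64
2-10-l,PVHA,61.25,2.91
2-10-l,NVHA,56.57,2.33
2-10-l,PVLA,58.80,2.56
2-10-l,NVLA,61.94,3.06
2-2,BASELINE,99.91,0.04
2-2,0VLA,14.03,1.00
2-2,PVHA,23.38,1.24
2-2,NVHA,34.31,1.71
2-2,PVLA,25.09,1.23
2-2,NVLA,25.46,1.84
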