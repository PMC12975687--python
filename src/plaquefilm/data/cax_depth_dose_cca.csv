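depth_mm,reference,measurement,difference_pp
0.83,1.35,1.34,-0.16
1.00,1.30,1.29,-0.70
2.00,1.00,1.00,0.00
3.00,0.74,0.75,0.93
4.00,0.52,0.54,1.93
5.00,0.36,0.37,1.34
6.00,0.23,0.24,0.62
7.00,0.15,0.14,-0.28
8.00,0.09,0.08,-0.94
9.00,0.05,0.04,-1.57
10.00,0.03,0.02,-1.31
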