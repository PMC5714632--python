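energy_kev,weight
30,0.020
40,0.080
50,0.130
60,0.160
70,0.160
80,0.150
90,0.120
100,0.090
110,0.060
120,0.030
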