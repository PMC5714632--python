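energy_kev,air,water,lung,adipose,bone,aluminum
10,5.120,5.329,5.280,3.270,28.51,26.23
15,1.614,1.673,1.660,1.083,9.032,7.955
20,0.7779,0.8096,0.8030,0.5625,4.001,3.441
30,0.3538,0.3756,0.3720,0.3045,1.331,1.128
40,0.2485,0.2683,0.2660,0.2373,0.6655,0.5685
50,0.2080,0.2269,0.2250,0.2080,0.4242,0.3681
60,0.1875,0.2059,0.2040,0.1930,0.3148,0.2778
80,0.1662,0.1837,0.1820,0.1750,0.2229,0.2018
100,0.1541,0.1707,0.1690,0.1638,0.1855,0.1704
150,0.1356,0.1505,0.1490,0.1452,0.1480,0.1378
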