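brix_pct,density_g_per_ml
0,0.99823
2,1.0060
4,1.0139
6,1.0219
8,1.0299
10,1.0381
12,1.0465
14,1.0549
16,1.0635
18,1.0722
20,1.0810
22,1.0899
24,1.0990
26,1.1082
28,1.1175
30,1.1270
32,1.1366
34,1.1464
36,1.1562
38,1.1663
40,1.1765
42,1.1868
44,1.1972
46,1.2079
48,1.2186
50,1.2295
52,1.2406
54,1.2518
56,1.2632
58,1.2747
60,1.2864
62,1.2983
64,1.3103
66,1.3224
68,1.3348
70,1.3472
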