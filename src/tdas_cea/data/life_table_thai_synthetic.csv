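age,qx
0,0.008000
1,0.001219
2,0.001221
3,0.001224
4,0.001226
5,0.001229
6,0.001232
7,0.001236
8,0.001240
9,0.001244
10,0.001249
11,0.001254
12,0.001260
13,0.001266
14,0.001273
15,0.001281
16,0.001290
17,0.001299
18,0.001310
19,0.001322
20,0.001335
21,0.001349
22,0.001365
23,0.001383
24,0.001403
25,0.001424
26,0.001449
27,0.001475
28,0.001505
29,0.001538
30,0.001574
31,0.001614
32,0.001658
33,0.001708
34,0.001762
35,0.001823
36,0.001889
37,0.001963
38,0.002045
39,0.002136
40,0.002237
41,0.002348
42,0.002471
43,0.002608
44,0.002759
45,0.002926
46,0.003112
47,0.003317
48,0.003544
49,0.003796
50,0.004075
51,0.004384
52,0.004725
53,0.005104
54,0.005523
55,0.005988
56,0.006502
57,0.007071
58,0.007701
59,0.008400
60,0.009173
61,0.010029
62,0.010977
63,0.012027
64,0.013189
65,0.014477
66,0.015902
67,0.017481
68,0.019230
69,0.021166
70,0.023310
71,0.025684
72,0.028313
73,0.031225
74,0.034449
75,0.038019
76,0.041973
77,0.046351
78,0.051200
79,0.056569
80,0.062514
81,0.069099
82,0.076390
83,0.084464
84,0.093405
85,0.103306
86,0.114271
87,0.126413
88,0.139859
89,0.154748
90,0.171237
91,0.189496
92,0.209716
93,0.232107
94,0.256903
95,0.284361
96,0.314768
97,0.348440
98,0.385728
99,0.427020
100,1.000000
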