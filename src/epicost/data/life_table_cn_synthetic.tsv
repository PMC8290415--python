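age	annual_death_probability
0	0.004438
1	0.000751
2	0.000754
3	0.000757
4	0.000761
5	0.000465
6	0.000470
7	0.000475
8	0.000480
9	0.000486
10	0.000493
11	0.000500
12	0.000508
13	0.000517
14	0.000527
15	0.000538
16	0.000550
17	0.000563
18	0.000577
19	0.000593
20	0.000611
21	0.000630
22	0.000651
23	0.000675
24	0.000700
25	0.000728
26	0.000759
27	0.000794
28	0.000831
29	0.000873
30	0.000918
31	0.000969
32	0.001024
33	0.001085
34	0.001152
35	0.001225
36	0.001306
37	0.001396
38	0.001494
39	0.001602
40	0.001721
41	0.001852
42	0.001996
43	0.002155
44	0.002330
45	0.002522
46	0.002734
47	0.002966
48	0.003223
49	0.003505
50	0.003815
51	0.004156
52	0.004532
53	0.004946
54	0.005400
55	0.005901
56	0.006451
57	0.007057
58	0.007723
59	0.008456
60	0.009263
61	0.010149
62	0.011124
63	0.012196
64	0.013375
65	0.014671
66	0.016096
67	0.017662
68	0.019383
69	0.021273
70	0.023350
71	0.025631
72	0.028136
73	0.030885
74	0.033903
75	0.037214
76	0.040845
77	0.044827
78	0.049190
79	0.053970
80	0.059204
81	0.064932
82	0.071197
83	0.078044
84	0.085523
85	0.093686
86	0.102586
87	0.112283
88	0.122835
89	0.134306
90	0.146759
91	0.160260
92	0.174874
93	0.190667
94	0.207702
95	0.226039
96	0.245733
97	0.266833
98	0.289377
99	0.313392
100	1.000000
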