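age,annual_death_prob
0,0.0005229421108523535
1,0.0005252409214639986
2,0.0005277688228055855
3,0.0005305486445195129
4,0.0005336054911572186
5,0.0005369669688379819
6,0.0005406634344840011
7,0.0005447282698816114
8,0.0005491981830360038
9,0.0005541135395391583
10,0.000559518726936159
11,0.000565462555373708
12,0.0005719986981396197
13,0.0005791861760631178
14,0.0005870898901345623
15,0.0005957812071426538
16,0.0006053386035957953
17,0.0006158483737223053
18,0.0006274054079145053
19,0.000640114048613305
20,0.0006540890313220249
21,0.0006694565191984747
22,0.0006863552405090845
23,0.0007049377391441514
24,0.0007253717494012379
25,0.0007478417073454313
26,0.0007725504122677584
27,0.0007997208530897693
28,0.0008295982160232418
29,0.0008624520913855793
30,0.0008985788992283972
31,0.0009383045553496006
32,0.0009819874013666796
33,0.0010300214248214479
34,0.0010828397978123183
35,0.0011409187653960151
36,0.0012047819180158736
37,0.0012750048854983653
38,0.001352220493750056
39,0.001437124429203629
40,0.001530481460326083
41,0.001633132270152271
42,0.001746000958856575
43,0.0018701032808684515
44,0.0020065556869900414
45,0.002156585248426879
46,0.002321540546616152
47,0.002502903620263175
48,0.0027023030691009087
49,0.002921528422591524
50,0.0031625458911063165
51,0.0034275156270658913
52,0.0037188106340932947
53,0.004039037473418272
54,0.004391058928537084
55,0.004778018801441686
56,0.005203369026489213
57,0.005670899301103205
58,0.006184769445799709
59,0.00674954471934297
60,0.007370234327863878
61,0.008052333379184873
62,0.008801868544948466
63,0.009625447702872991
64,0.010530313838869931
65,0.011524403492965907
66,0.01261641003292402
67,0.013815852033801979
68,0.015133147028831284
69,0.016579690874972686
70,0.018167942942937443
71,0.019911517293507486
72,0.021825279936235398
73,0.02392545217900488
74,0.0262297199626913
75,0.028757348928625026
76,0.031529304781179546
77,0.034568378275893874
78,0.03789931387636469
79,0.04154894077064819
80,0.04554630450889008
81,0.049922797005769404
82,0.054712282030488835
83,0.059951212568788326
84,0.06567873557069948
85,0.07193677857931347
86,0.07877011155551461
87,0.08622637585975312
88,0.09435607081648001
89,0.10321248656907478
90,0.11285157004184454
91,0.12333170878410926
92,0.13471341532302994
93,0.14705889246656934
94,0.16043145788084212
95,0.1748948043675489
96,0.19051207079352317
97,0.2073446978501
98,0.22545104310057984
99,1.0
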