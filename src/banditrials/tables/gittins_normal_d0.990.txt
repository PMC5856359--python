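# gittins index table: normal reward process, known variance
# discount=0.99
# grid_half_width=6.0
# grid_points=801
# horizon=1375
# horizon_tol=1e-06
# kernel_cut=8.0
# tol=0.0001
# columns: n value
1 1.57681274414
2 1.04213260563
3 0.806638705267
4 0.668184976189
5 0.575121682722
6 0.507517349044
7 0.455784745527
8 0.414658173841
9 0.381129928321
10 0.353069021907
11 0.329303207753
12 0.308893173168
13 0.29101662368
14 0.275298386802
15 0.261356957925
16 0.248874013677
17 0.237642631904
18 0.227427127352
19 0.21813786832
20 0.209641537357
21 0.201821951503
22 0.194651633632
23 0.187961225181
24 0.181718326658
25 0.175982372721
26 0.170544293244
27 0.165555320116
28 0.160821848403
29 0.156330335481
30 0.152144887412
32 0.144433276385
34 0.137444387912
36 0.131245009341
38 0.125497156081
40 0.120351420227
42 0.115574191969
44 0.111195158209
46 0.107182532732
48 0.103402005773
50 0.0999414708584
52 0.09665342986
54 0.0936957957397
56 0.0908580266741
58 0.0881352648508
60 0.0856969416461
65 0.0799660755711
70 0.0750754772995
75 0.0706892740728
80 0.066893653688
85 0.0634182419459
90 0.0603606476046
95 0.057555568383
100 0.0549816201174
110 0.0505419998033
120 0.046785438298
130 0.043538880793
140 0.0407548157256
150 0.0382888398109
160 0.0361042951778
170 0.0341692874538
180 0.0323873418642
190 0.0308115606071
200 0.0294194803661
220 0.0269438170821
240 0.0248601732049
260 0.0231074789868
280 0.0215178083925
300 0.0201868633831
320 0.0189936919782
340 0.017924032457
360 0.0170390214115
380 0.0161717008357
400 0.0153941614914
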