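# gittins index table: normal reward process, known variance
# discount=0.95
# grid_half_width=6.0
# grid_points=801
# horizon=270
# horizon_tol=1e-06
# kernel_cut=8.0
# tol=0.0001
# columns: n value
1 0.995819091797
2 0.634358780555
3 0.478186591982
4 0.387905991788
5 0.328091956695
6 0.285263914123
7 0.252892083314
8 0.227455322197
9 0.206898197678
10 0.189905055325
11 0.175664344122
12 0.163423144501
13 0.152821999784
14 0.14364481181
15 0.135498570048
16 0.128200683343
17 0.12172496021
18 0.115923552503
19 0.110614933093
20 0.105810738575
21 0.101412832597
22 0.0973371966063
23 0.0935835918875
24 0.0901961694122
25 0.0869658783506
26 0.0840572382482
27 0.0812778394783
28 0.0786219393843
29 0.0762395620765
30 0.0739583892734
32 0.0697976798557
34 0.0660617022482
36 0.0627721109422
38 0.0597552152823
40 0.0569876799596
42 0.0545050214464
44 0.0522256720348
46 0.0501329694117
48 0.0481868315257
50 0.0464488926614
52 0.0448076945348
54 0.0432578521632
56 0.0417942803143
58 0.040495759399
60 0.0391859368543
65 0.0363792611952
70 0.033911458643
75 0.0318089755018
80 0.0298933341242
85 0.0282686074945
90 0.0267819191625
95 0.0254215412649
100 0.0241767423488
110 0.0220788228801
120 0.0203291974979
130 0.0187880235773
140 0.0175077630479
150 0.0163750325404
160 0.0154407027459
170 0.0145461686404
180 0.0137547156135
190 0.0130544651814
200 0.0124349076703
220 0.0113094632928
240 0.0104341934943
260 0.00960293594244
280 0.00890480948291
300 0.00831849233916
320 0.00782607755047
340 0.00741252606778
360 0.00699948457983
380 0.00665582115431
400 0.00631007134203
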