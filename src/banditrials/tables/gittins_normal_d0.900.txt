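# gittins index table: normal reward process, known variance
# discount=0.9
# grid_half_width=6.0
# grid_points=801
# horizon=132
# horizon_tol=1e-06
# kernel_cut=8.0
# tol=0.0001
# columns: n value
1 0.746612548828
2 0.466208338097
3 0.346556575494
4 0.278104657271
5 0.233279979044
6 0.201362955622
7 0.177413421298
8 0.158681663523
9 0.143658918477
10 0.131344364701
11 0.121003331495
12 0.112203747496
13 0.104608443426
14 0.0980023665678
15 0.0921862856664
16 0.0870436349999
17 0.0824979177562
18 0.0783200683641
19 0.0746336776063
20 0.0712389473157
21 0.0681825611139
22 0.0653653592555
23 0.0627684086318
24 0.0603122107031
25 0.0581088871946
26 0.0560784022555
27 0.0541520193273
28 0.0523782605428
29 0.0506937093534
30 0.0490938792443
32 0.0462292147323
34 0.0436777991714
36 0.0414054994274
38 0.0393824511284
40 0.037503624046
42 0.0358339391756
44 0.034280023471
46 0.0329027562645
48 0.0316182931959
50 0.0303566732575
52 0.0292437724228
54 0.0282649318443
56 0.027292978429
58 0.0263865179685
60 0.0255411373632
65 0.0236641195435
70 0.0220146535769
75 0.0206322773278
80 0.01939299862
85 0.0182820046222
90 0.0172860158625
95 0.0163931275017
100 0.0155926670377
110 0.0142269156827
120 0.0130558905951
130 0.0121067338915
140 0.0112380003484
150 0.0104692268605
160 0.0099011685007
170 0.00932560899083
180 0.00875256699613
190 0.00834301629747
200 0.00791966615841
220 0.00721238630777
240 0.00664048424105
260 0.00611835652115
280 0.00570024643296
300 0.00531308603863
320 0.00498141945236
340 0.00471971378663
360 0.00442384113184
380 0.00419500212541
400 0.00401800945637
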