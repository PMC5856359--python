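# gittins index table: normal reward process, known variance
# discount=0.995
# grid_half_width=6.0
# grid_points=801
# horizon=2757
# horizon_tol=1e-06
# kernel_cut=8.0
# tol=0.0001
# columns: n value
1 1.81973266602
2 1.21705377045
3 0.950377830477
4 0.792824536647
5 0.686505118393
6 0.6089103255
7 0.549343669031
8 0.50187284906
9 0.463002742192
10 0.430442973545
11 0.402766130394
12 0.378875762249
13 0.357942017675
14 0.339531456905
15 0.323114137515
16 0.308406946036
17 0.295092342454
18 0.283044327851
19 0.272012665038
20 0.261914860173
21 0.252612654348
22 0.244046454373
23 0.236042672297
24 0.228680204976
25 0.221745695942
26 0.215268270846
27 0.209219488093
28 0.203521821297
29 0.198180446467
30 0.193101941631
32 0.183723932544
34 0.175298321729
36 0.16773304682
38 0.160782490659
40 0.154475420158
42 0.1486809621
44 0.143285901463
46 0.138332698986
48 0.13371993157
50 0.129490324852
52 0.125488620506
54 0.121702063821
56 0.118238536597
58 0.114901001941
60 0.111798061198
65 0.104729254575
70 0.0985791072316
75 0.0931122999748
80 0.0882762344979
85 0.0839144293986
90 0.0800633609222
95 0.0765114632142
100 0.0732347076755
110 0.0676014305737
120 0.062739491926
130 0.0586042301253
140 0.0549767532748
150 0.0517948962186
160 0.0489538612886
170 0.0463926973491
180 0.0441066802478
190 0.0420672652701
200 0.040249387562
220 0.0369391488226
240 0.0341971038704
260 0.0318630032108
280 0.0298141894364
300 0.0279554511586
320 0.0263822616513
340 0.0250023580508
360 0.0236916016224
380 0.0225214413236
400 0.0215460077749
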