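# synthetic Bethe-formula stopping table (Z/A=0.49919, I=85.7 eV); see scripts/generate_stopping_tables.py
energy_MeV,mass_stopping_power_MeV_cm2_g,csda_range_g_cm2
1,232.9343,0.0025401741
1.0474921,225.57573,0.0027473906
1.0972397,218.40661,0.0029715511
1.1493499,211.4249,0.0032140886
1.203935,204.62835,0.003476559
1.2611124,198.01454,0.0037606522
1.3210052,191.58087,0.0040682052
1.3837425,185.32462,0.0044012116
1.4494594,179.24293,0.0047618398
1.5182973,173.33286,0.005152444
1.5904044,167.59134,0.0055755831
1.665936,162.01526,0.0060340392
1.7450548,156.60142,0.0065308328
1.8279311,151.3466,0.0070692514
1.9147434,146.2475,0.0076528635
2.0056786,141.30083,0.0082855516
2.1009325,136.50324,0.0089715357
2.2007102,131.85141,0.0097154008
2.3052266,127.342,0.010522139
2.4147066,122.97165,0.011397169
2.5293861,118.73704,0.012346389
2.649512,114.63485,0.013376212
2.7753428,110.66181,0.014493608
2.9071497,106.81463,0.015706166
3.0452164,103.09008,0.017022127
3.1898401,99.484962,0.018450468
3.3413323,95.996116,0.02000094
3.5000192,92.620419,0.021684158
3.6662424,89.354793,0.02351167
3.84036,86.196209,0.025496025
4.0227467,83.141683,0.027650896
4.2137954,80.188284,0.029991136
4.4139174,77.333132,0.032532917
4.6235436,74.5734,0.035293832
4.8431254,71.906318,0.038293011
5.0731356,69.329167,0.041551295
5.3140695,66.839286,0.045091322
5.5664458,64.434072,0.048937756
5.830808,62.110975,0.053117418
6.1077253,59.867507,0.057659486
6.397794,57.701232,0.06259574
6.7016387,55.609775,0.067960712
7.0199136,53.590815,0.073792029
7.3533041,51.64209,0.080130595
7.7025279,49.761392,0.087020934
8.0683371,47.94657,0.094511516
8.4515194,46.195528,0.10265503
8.8528998,44.506225,0.11150888
9.2733426,42.876674,0.12113546
9.7137531,41.30494,0.13160271
10.17508,39.789143,0.14298454
10.658316,38.327453,0.15536133
11.164501,36.91809,0.16882065
11.694727,35.559327,0.18345762
12.250134,34.249485,0.19937587
12.831919,32.986932,0.21668806
13.441334,31.770085,0.23551675
14.079691,30.597406,0.25599538
14.748365,29.467404,0.2782689
15.448796,28.378632,0.30249521
16.182491,27.329686,0.32884586
16.951032,26.319204,0.35750752
17.756072,25.345869,0.38868326
18.599345,24.408401,0.42259369
19.482667,23.50556,0.45947902
20.40794,22.636147,0.49960007
21.377156,21.798998,0.54324061
22.392402,20.992988,0.59070912
23.455864,20.217028,0.64234064
24.569832,19.470061,0.69849983
25.736705,18.751066,0.75958225
26.958995,18.059057,0.82601828
28.239335,17.393076,0.89827517
29.58048,16.7522,0.97686041
30.985319,16.135534,1.0623256
32.456877,15.542214,1.1552691
33.998322,14.971404,1.256341
35.612974,14.422296,1.3662468
37.304309,13.89411,1.485752
39.075969,13.386091,1.6156877
40.931769,12.89751,1.7569547
42.875704,12.427664,1.9105312
44.911961,11.975872,2.0774765
47.044925,11.541478,2.2589398
49.279187,11.123847,2.4561667
51.619559,10.722368,2.6705057
54.071081,10.336449,2.9034194
56.63903,9.9655209,3.1564891
59.328936,9.6090321,3.4314285
62.146592,9.266452,3.7300913
65.098064,8.9372681,4.054482
68.189708,8.6209863,4.4067704
71.42818,8.3171296,4.7892988
74.820455,8.0252385,5.2046012
78.373835,7.7448694,5.6554122
82.095973,7.4755948,6.1446847
85.994883,7.2170027,6.6756067
90.078961,6.9686958,7.2516131
94.357,6.7302911,7.8764123
98.838212,6.5014196,8.5539945
103.53225,6.2817258,9.2886605
108.44921,6.070867,10.085039
113.59969,5.8685133,10.948106
118.99478,5.6743467,11.883218
124.64609,5.4880611,12.89612
130.5658,5.3093614,13.99299
136.76664,5.1379639,15.180452
143.26197,4.973595,16.465606
150.06579,4.8159918,17.856068
157.19273,4.6649007,19.35998
164.65814,4.520078,20.986066
172.4781,4.381289,22.74364
180.66945,4.2483079,24.642655
189.24982,4.1209175,26.693739
198.23769,3.9989087,28.908209
207.65241,3.8820806,31.298141
217.51426,3.7702397,33.87637
227.84447,3.6632,36.656553
238.66528,3.5607827,39.6532
250,3.4628158,42.881697
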