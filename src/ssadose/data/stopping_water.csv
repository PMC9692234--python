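# synthetic Bethe-formula stopping table (Z/A=0.55509, I=75.0 eV); see scripts/generate_stopping_tables.py
energy_MeV,mass_stopping_power_MeV_cm2_g,csda_range_g_cm2
1,269.70033,0.0021781735
1.0474921,261.03422,0.0023571929
1.0972397,252.60069,0.0025509574
1.1493499,244.39649,0.0027607195
1.203935,236.41816,0.0029878396
1.2611124,228.6621,0.0032337951
1.3210052,221.12457,0.0035001931
1.3837425,213.8017,0.0037887776
1.4494594,206.68955,0.0041014461
1.5182973,199.78407,0.0044402593
1.5904044,193.08114,0.0048074577
1.665936,186.57662,0.0052054774
1.7450548,180.26629,0.0056369642
1.8279311,174.14594,0.0061047983
1.9147434,168.21132,0.0066121068
2.0056786,162.45819,0.0071622924
2.1009325,156.88229,0.007759055
2.2007102,151.47939,0.0084064149
2.3052266,146.24529,0.0091087501
2.4147066,141.17579,0.0098708139
2.5293861,136.26674,0.010697782
2.649512,131.51403,0.011595282
2.7753428,126.91358,0.012569431
2.9071497,122.46137,0.013626892
3.0452164,118.15342,0.014774902
3.1898401,113.98581,0.016021342
3.3413323,109.9547,0.017374781
3.5000192,106.05628,0.018844541
3.6662424,102.28681,0.020440771
3.84036,98.642641,0.022174501
4.0227467,95.12016,0.024057747
4.2137954,91.715838,0.026103569
4.4139174,88.426215,0.028326186
4.6235436,85.2479,0.030741071
4.8431254,82.177576,0.03336505
5.0731356,79.211995,0.036216458
5.3140695,76.347984,0.039315212
5.5664458,73.582442,0.042683018
5.830808,70.912339,0.04634348
6.1077253,68.334718,0.050322285
6.397794,65.846696,0.054647412
6.7016387,63.445459,0.059349266
7.0199136,61.128264,0.064460984
7.3533041,58.89244,0.070018595
7.7025279,56.735383,0.07606132
8.0683371,54.654561,0.082631861
8.4515194,52.647508,0.089776646
8.8528998,50.711824,0.097546268
9.2733426,48.845177,0.10599571
9.7137531,47.045299,0.11518487
10.17508,45.309984,0.12517891
10.658316,43.637093,0.1360487
11.164501,42.024544,0.14787147
11.694727,40.470317,0.1607311
12.250134,38.972453,0.174719
12.831919,37.529048,0.18993456
13.441334,36.138257,0.20648591
14.079691,34.798289,0.2244908
14.748365,33.507408,0.24407715
15.448796,32.263931,0.2653843
16.182491,31.066226,0.2885637
16.951032,29.912712,0.31378012
17.756072,28.801859,0.34121286
18.599345,27.732183,0.37105671
19.482667,26.702246,0.40352379
20.40794,25.710659,0.43884445
21.377156,24.756076,0.47726935
22.392402,23.837192,0.51907097
23.455864,22.952748,0.5645453
24.569832,22.101524,0.61401453
25.736705,21.282339,0.6678282
26.958995,20.494054,0.72636663
28.239335,19.735564,0.79004278
29.58048,19.005803,0.85930521
30.985319,18.30374,0.93464155
32.456877,17.628378,1.0165807
33.998322,16.978755,1.1056975
35.612974,16.35394,1.2026157
37.304309,15.753035,1.3080122
39.075969,15.175171,1.4226222
40.931769,14.61951,1.5472422
42.875704,14.085242,1.6827375
44.911961,13.571587,1.8300452
47.044925,13.077789,1.990182
49.279187,12.60312,2.1642498
51.619559,12.146877,2.3534419
54.071081,11.708383,2.5590527
56.63903,11.286982,2.7824813
59.328936,10.882044,3.0252447
62.146592,10.492959,3.2889833
65.098064,10.119141,3.5754717
68.189708,9.7600223,3.8866308
71.42818,9.4150576,4.224534
74.820455,9.0837202,4.5914251
78.373835,8.7655024,4.9897253
82.095973,8.4599151,5.4220496
85.994883,8.1664865,5.8912212
90.078961,7.8847624,6.4002824
94.357,7.6143048,6.9525175
98.838212,7.3546918,7.5514611
103.53225,7.1055171,8.2009231
108.44921,6.8663892,8.9050041
113.59969,6.636931,9.6681125
118.99478,6.4167795,10.494995
124.64609,6.2055849,11.390742
130.5658,6.0030108,12.360828
136.76664,5.808733,13.411123
143.26197,5.6224395,14.54792
150.06579,5.4438302,15.77797
157.19273,5.2726161,17.108491
164.65814,5.1085191,18.547214
172.4781,4.9512717,20.102398
180.66945,4.8006166,21.782868
189.24982,4.6563061,23.598046
198.23769,4.518102,25.557969
207.65241,4.3857754,27.673346
217.51426,4.259106,29.955557
227.84447,4.1378819,32.41672
238.66528,4.0218995,35.069701
250,3.910963,37.928151
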