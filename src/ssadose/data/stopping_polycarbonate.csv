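# synthetic Bethe-formula stopping table (Z/A=0.52697, I=73.1 eV); see scripts/generate_stopping_tables.py
energy_MeV,mass_stopping_power_MeV_cm2_g,csda_range_g_cm2
1,257.98881,0.0022740645
1.0474921,249.67339,0.0024612203
1.0972397,241.58278,0.0026638119
1.1493499,233.7137,0.0028831516
1.203935,226.06269,0.0031206645
1.2611124,218.62619,0.0033778988
1.3210052,211.40046,0.0036565384
1.3837425,204.38171,0.0039584107
1.4494594,197.56602,0.0042855045
1.5182973,190.94943,0.004639979
1.5904044,184.52789,0.0050241824
1.665936,178.29734,0.005440668
1.7450548,172.25368,0.0058922089
1.8279311,166.39276,0.0063818237
1.9147434,160.71046,0.0069127905
2.0056786,155.20265,0.0074886763
2.1009325,149.86518,0.0081133592
2.2007102,144.69395,0.0087910541
2.3052266,139.68487,0.0095263508
2.4147066,134.83387,0.010324232
2.5293861,130.13693,0.011190126
2.649512,125.59007,0.01212993
2.7753428,121.18933,0.013150062
2.9071497,116.93084,0.014257505
3.0452164,112.81074,0.015459848
3.1898401,108.82526,0.016765358
3.3413323,104.97067,0.018183019
3.5000192,101.24331,0.019722607
3.6662424,97.639563,0.021394766
3.84036,94.155909,0.023211064
4.0227467,90.788874,0.025184104
4.2137954,87.535055,0.027327583
4.4139174,84.39112,0.029656415
4.6235436,81.353805,0.03218683
4.8431254,78.419916,0.034936476
5.0731356,75.586332,0.037924588
5.3140695,72.849998,0.041172058
5.5664458,70.207934,0.044701655
5.830808,67.657229,0.048538144
6.1077253,65.19504,0.052708471
6.397794,62.818597,0.057241988
6.7016387,60.525198,0.062170597
7.0199136,58.31221,0.067529063
7.3533041,56.177069,0.073355188
7.7025279,54.117275,0.079690124
8.0683371,52.130398,0.086578678
8.4515194,50.214073,0.094069563
8.8528998,48.365998,0.10221587
9.2733426,46.583936,0.1110753
9.7137531,44.865713,0.12071069
10.17508,43.209215,0.13119044
10.658316,41.61239,0.14258891
11.164501,40.073244,0.15498715
11.694727,38.589842,0.1684732
12.250134,37.160306,0.18314298
12.831919,35.782812,0.19910081
13.441334,34.455594,0.21646018
14.079691,33.176936,0.23534466
14.748365,31.945177,0.25588852
15.448796,30.758704,0.27823803
16.182491,29.615957,0.30255214
16.951032,28.515421,0.3290038
17.756072,27.455632,0.35778121
18.599345,26.435171,0.38908886
19.482667,25.452661,0.42314941
20.40794,24.506774,0.46020466
21.377156,23.596221,0.50051774
22.392402,22.719756,0.54437471
23.455864,21.876173,0.59208629
24.569832,21.064305,0.64399073
25.736705,20.283026,0.70045498
26.958995,19.531242,0.76187832
28.239335,18.807901,0.82869433
29.58048,18.111982,0.90137393
30.985319,17.442499,0.9804291
32.456877,16.798501,1.0664151
33.998322,16.179066,1.1599356
35.612974,15.583307,1.2616454
37.304309,15.010363,1.3722555
39.075969,14.459406,1.4925374
40.931769,13.929635,1.6233278
42.875704,13.420276,1.7655353
44.911961,12.930583,1.9201437
47.044925,12.459834,2.0882208
49.279187,12.007335,2.2709237
51.619559,11.572414,2.4695054
54.071081,11.154423,2.6853251
56.63903,10.752738,2.9198523
59.328936,10.366756,3.1746798
62.146592,9.9958942,3.4515306
65.098064,9.6395933,3.7522682
68.189708,9.2973121,4.07891
71.42818,8.9685293,4.4336335
74.820455,8.6527422,4.8187952
78.373835,8.3494663,5.236938
82.095973,8.0582345,5.6908084
85.994883,7.7785967,6.1833714
90.078961,7.5101194,6.7178224
94.357,7.2523844,7.2976111
98.838212,7.0049893,7.9264497
103.53225,6.7675461,8.60834
108.44921,6.5396814,9.3475891
113.59969,6.3210354,10.148828
118.99478,6.1112616,11.017041
124.64609,5.9100264,11.957576
130.5658,5.7170087,12.976184
136.76664,5.5318992,14.079031
143.26197,5.3544005,15.272726
150.06579,5.184226,16.564363
157.19273,5.0211002,17.96152
164.65814,4.8647577,19.472323
172.4781,4.7149435,21.105447
180.66945,4.5714121,22.87016
189.24982,4.4339272,24.776363
198.23769,4.3022617,26.834599
207.65241,4.1761973,29.056118
217.51426,4.0555238,31.452877
227.84447,3.9400393,34.037605
238.66528,3.8295495,36.823821
250,3.7238678,39.825865
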