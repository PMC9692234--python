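# synthetic Bethe-formula stopping table (Z/A=0.47706, I=311.0 eV); see scripts/generate_stopping_tables.py
energy_MeV,mass_stopping_power_MeV_cm2_g,csda_range_g_cm2
1,133.88355,0.0050258063
1.0474921,130.86744,0.0053846209
1.0972397,127.85028,0.0057692439
1.1493499,124.8384,0.0061817498
1.203935,121.83751,0.0066243824
1.2611124,118.85282,0.0070995698
1.3210052,115.88905,0.0076099427
1.3837425,112.95043,0.0081583463
1.4494594,110.04081,0.008747865
1.5182973,107.16359,0.009381837
1.5904044,104.32182,0.01006388
1.665936,101.51823,0.010797913
1.7450548,98.755202,0.011588182
1.8279311,96.034828,0.012439292
1.9147434,93.358931,0.013356228
2.0056786,90.729083,0.014344399
2.1009325,88.146619,0.015409669
2.2007102,85.612658,0.016558392
2.3052266,83.128121,0.017797465
2.4147066,80.693746,0.019134359
2.5293861,78.310103,0.020577187
2.649512,75.977606,0.022134741
2.7753428,73.696528,0.023816562
2.9071497,71.467011,0.025633008
3.0452164,69.28908,0.027595303
3.1898401,67.16265,0.029715644
3.3413323,65.08754,0.032007252
3.5000192,63.063477,0.034484484
3.6662424,61.090109,0.037162926
3.84036,59.167011,0.040059484
4.0227467,57.29369,0.043192529
4.2137954,55.469598,0.046581984
4.4139174,53.694132,0.050249494
4.6235436,51.966643,0.05421856
4.8431254,50.286441,0.058514684
5.0731356,48.6528,0.063165594
5.3140695,47.064963,0.068201353
5.5664458,45.522144,0.073654652
5.830808,44.023537,0.079560973
6.1077253,42.568315,0.08595885
6.397794,41.155635,0.092890172
6.7016387,39.784642,0.10040038
7.0199136,38.454471,0.10853889
7.3533041,37.164249,0.11735935
7.7025279,35.913098,0.12692004
8.0683371,34.70014,0.13728429
8.4515194,33.524493,0.14852086
8.8528998,32.385279,0.16070452
9.2733426,31.281622,0.1739164
9.7137531,30.21265,0.18824473
10.17508,29.177499,0.20378532
10.658316,28.175309,0.22064222
11.164501,27.205231,0.23892862
11.694727,26.266424,0.25876727
12.250134,25.358059,0.28029172
12.831919,24.479315,0.30364694
13.441334,23.629386,0.32899041
14.079691,22.807476,0.35649336
14.748365,22.012803,0.38634155
15.448796,21.244599,0.41873701
16.182491,20.502107,0.45389899
16.951032,19.784588,0.4920657
17.756072,19.091314,0.53349599
18.599345,18.421574,0.57847067
19.482667,17.77467,0.62729511
20.40794,17.149921,0.6803005
21.377156,16.546659,0.73784669
22.392402,15.964232,0.8003244
23.455864,15.402002,0.86815748
24.569832,14.859347,0.94180671
25.736705,14.335661,1.0217713
26.958995,13.83035,1.1085939
28.239335,13.342838,1.2028627
29.58048,12.872562,1.3052161
30.985319,12.418973,1.4163473
32.456877,11.981538,1.5370069
33.998322,11.559736,1.6680103
35.612974,11.153062,1.8102406
37.304309,10.761025,1.9646558
39.075969,10.383147,2.1322944
40.931769,10.018961,2.314281
42.875704,9.6680179,2.5118356
44.911961,9.3298775,2.7262779
47.044925,9.0041144,2.9590387
49.279187,8.690315,3.2116665
51.619559,8.388078,3.4858366
54.071081,8.097014,3.7833645
56.63903,7.8167454,4.1062107
59.328936,7.5469062,4.4564984
62.146592,7.2871412,4.8365215
65.098064,7.0371064,5.2487589
68.189708,6.7964686,5.6958913
71.42818,6.5649048,6.1808098
74.820455,6.3421023,6.7066395
78.373835,6.1277583,7.2767498
82.095973,5.9215798,7.8947763
85.994883,5.7232829,8.5646402
90.078961,5.5325934,9.2905634
94.357,5.3492456,10.077099
98.838212,5.1729827,10.929144
103.53225,5.0035565,11.85197
108.44921,4.8407269,12.851248
113.59969,4.6842617,13.933066
118.99478,4.5339369,15.103977
124.64609,4.3895356,16.371
130.5658,4.2508486,17.741678
136.76664,4.1176738,19.22409
143.26197,3.9898159,20.826894
150.06579,3.8670864,22.559364
157.19273,3.7493035,24.431408
164.65814,3.6362915,26.453635
172.4781,3.527881,28.637361
180.66945,3.4239086,30.99467
189.24982,3.3242166,33.53845
198.23769,3.2286528,36.282421
207.65241,3.1370708,39.241203
217.51426,3.049329,42.430325
227.84447,2.9652912,45.866299
238.66528,2.884826,49.566646
250,2.8078068,53.549936
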