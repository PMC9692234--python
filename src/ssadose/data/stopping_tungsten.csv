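# synthetic Bethe-formula stopping table (Z/A=0.40252, I=727.0 eV); see scripts/generate_stopping_tables.py
energy_MeV,mass_stopping_power_MeV_cm2_g,csda_range_g_cm2
1,63.646974,0.014404508
1.0474921,63.334554,0.015152435
1.0972397,62.920039,0.015940409
1.1493499,62.413338,0.016771889
1.203935,61.823671,0.017650559
1.2611124,61.159612,0.018580359
1.3210052,60.429128,0.019565504
1.3837425,59.639616,0.020610514
1.4494594,58.797938,0.021720248
1.5182973,57.910458,0.022899924
1.5904044,56.983067,0.024155161
1.665936,56.021217,0.025492011
1.7450548,55.029949,0.026916996
1.8279311,54.013916,0.028437153
1.9147434,52.97741,0.03006007
2.0056786,51.924385,0.031793942
2.1009325,50.858479,0.033647622
2.2007102,49.783034,0.035630667
2.3052266,48.701113,0.037753418
2.4147066,47.615525,0.040027039
2.5293861,46.528834,0.042463613
2.649512,45.443382,0.045076206
2.7753428,44.361298,0.047878947
2.9071497,43.284517,0.050887138
3.0452164,42.214792,0.054117322
3.1898401,41.153705,0.057587423
3.3413323,40.102682,0.061316833
3.5000192,39.062999,0.065326551
3.6662424,38.035798,0.06963933
3.84036,37.022092,0.07427979
4.0227467,36.02278,0.079274632
4.2137954,35.038648,0.084652748
4.4139174,34.070384,0.090445465
4.6235436,33.11858,0.096686729
4.8431254,32.183743,0.1034133
5.0731356,31.266301,0.11066508
5.3140695,30.366606,0.11848525
5.5664458,29.484945,0.12692066
5.830808,28.621541,0.13602209
6.1077253,27.776559,0.14584458
6.397794,26.950113,0.15644787
6.7016387,26.142269,0.16789665
7.0199136,25.353047,0.18026115
7.3533041,24.582429,0.19361748
7.7025279,23.83036,0.20804822
8.0683371,23.09675,0.22364293
8.4515194,22.381481,0.24049872
8.8528998,21.684407,0.25872102
9.2733426,21.005358,0.27842408
9.7137531,20.344142,0.2997319
10.17508,19.700546,0.32277903
10.658316,19.074342,0.34771133
11.164501,18.465285,0.37468724
11.694727,17.873116,0.40387839
12.250134,17.297565,0.43547121
12.831919,16.738353,0.46966787
13.441334,16.195191,0.50668764
14.079691,15.667781,0.54676866
14.748365,15.155822,0.59016892
15.448796,14.659006,0.6371687
16.182491,14.177023,0.68807178
16.951032,13.709558,0.74320781
17.756072,13.256295,0.80293455
18.599345,12.816917,0.86763973
19.482667,12.391106,0.93774446
20.40794,11.978546,1.0137049
21.377156,11.578919,1.0960163
22.392402,11.191912,1.1852156
23.455864,10.817211,1.2818847
24.569832,10.454506,1.3866556
25.736705,10.10349,1.5002122
26.958995,9.7638577,1.6232973
28.239335,9.4353096,1.7567151
29.58048,9.117549,1.9013377
30.985319,8.8102833,2.0581107
32.456877,8.5132245,2.2280576
33.998322,8.2260894,2.4122889
35.612974,7.9485992,2.6120062
37.304309,7.6804805,2.8285117
39.075969,7.4214647,3.0632161
40.931769,7.1712884,3.3176451
42.875704,6.9296936,3.5934529
44.911961,6.6964275,3.8924271
47.044925,6.4712427,4.2165039
49.279187,6.2538974,4.5677774
51.619559,6.0441551,4.9485112
54.071081,5.8417848,5.3611558
56.63903,5.6465609,5.8083559
59.328936,5.4582632,6.2929729
62.146592,5.2766772,6.8180962
65.098064,5.1015934,7.3870614
68.189708,4.9328079,8.0034729
71.42818,4.770122,8.6712149
74.820455,4.6133423,9.3944832
78.373835,4.4622806,10.177798
82.095973,4.3167536,11.026032
85.994883,4.1765834,11.944439
90.078961,4.0415967,12.938669
94.357,3.9116254,14.014813
98.838212,3.7865061,15.179416
103.53225,3.6660801,16.439519
108.44921,3.5501934,17.80269
113.59969,3.4386966,19.277052
118.99478,3.3314446,20.871336
124.64609,3.2282968,22.594892
130.5658,3.1291171,24.457759
136.76664,3.0337732,26.470683
143.26197,2.9421372,28.645169
150.06579,2.854085,30.993538
157.19273,2.7694967,33.52894
164.65814,2.688256,36.265443
172.4781,2.6102504,39.218048
180.66945,2.5353711,42.402759
189.24982,2.4635128,45.836635
198.23769,2.3945737,49.537819
207.65241,2.3284554,53.525637
217.51426,2.2650626,57.820595
227.84447,2.2043036,62.444485
238.66528,2.1460893,67.420413
250,2.090334,72.772847
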