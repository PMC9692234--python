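# synthetic Bethe-formula stopping table (Z/A=0.45711, I=324.4 eV); see scripts/generate_stopping_tables.py
energy_MeV,mass_stopping_power_MeV_cm2_g,csda_range_g_cm2
1,125.50238,0.005402627
1.0474921,122.73835,0.005785303
1.0972397,119.96761,0.0061952972
1.1493499,117.19645,0.0066348023
1.203935,114.43064,0.0071061894
1.2611124,111.67538,0.007612024
1.3210052,108.93542,0.008155085
1.3837425,106.21503,0.0087383773
1.4494594,103.5181,0.0093651581
1.5182973,100.8481,0.010038952
1.5904044,98.208126,0.010763578
1.665936,95.600968,0.011543173
1.7450548,93.029085,0.012382218
1.8279311,90.494646,0.013285571
1.9147434,87.999553,0.014258495
2.0056786,85.545459,0.015306693
2.1009325,83.133784,0.016436353
2.2007102,80.765738,0.017654174
2.3052266,78.442331,0.018967432
2.4147066,76.164394,0.020384004
2.5293861,73.93259,0.021912444
2.649512,71.747428,0.023562022
2.7753428,69.609277,0.025342795
2.9071497,67.518376,0.02726568
3.0452164,65.474845,0.029342508
3.1898401,63.478699,0.03158613
3.3413323,61.52985,0.034010481
3.5000192,59.628124,0.036630686
3.6662424,57.773265,0.039463167
3.84036,55.96494,0.042525731
4.0227467,54.202755,0.045837732
4.2137954,52.486253,0.049420153
4.4139174,50.814923,0.053295791
4.6235436,49.188209,0.057489394
4.8431254,47.605511,0.062027816
5.0731356,46.066192,0.066940252
5.3140695,44.569581,0.072258355
5.5664458,43.114982,0.078016539
5.830808,41.70167,0.084252157
6.1077253,40.328904,0.091005769
6.397794,38.995921,0.098321464
6.7016387,37.701947,0.10624707
7.0199136,36.446194,0.11483459
7.3533041,35.227868,0.12414047
7.7025279,34.046167,0.13422604
8.0683371,32.900284,0.14515794
8.4515194,31.789411,0.1570085
8.8528998,30.712739,0.16985639
9.2733426,29.669462,0.18378695
9.7137531,28.658774,0.19889298
10.17508,27.679877,0.21527528
10.658316,26.731975,0.23304326
11.164501,25.81428,0.25231597
11.694727,24.926014,0.27322251
12.250134,24.066404,0.29590329
12.831919,23.234689,0.32051077
13.441334,22.430118,0.34721053
14.079691,21.651948,0.3761826
14.748365,20.899452,0.40762227
15.448796,20.171912,0.44174194
16.182491,19.468623,0.47877208
16.951032,18.788891,0.5189631
17.756072,18.132039,0.56258706
18.599345,17.497399,0.60993913
19.482667,16.884319,0.66134026
20.40794,16.29216,0.71713849
21.377156,15.720296,0.77771202
22.392402,15.168115,0.84347141
23.455864,14.635021,0.91486208
24.569832,14.120428,0.99236815
25.736705,13.623767,1.0765142
26.958995,13.14448,1.1678703
28.239335,12.682026,1.2670545
29.58048,12.235875,1.3747374
30.985319,11.805511,1.4916473
32.456877,11.390433,1.6185726
33.998322,10.990149,1.7563698
35.612974,10.604186,1.9059667
37.304309,10.232078,2.0683693
39.075969,9.8733769,2.2446686
40.931769,9.527643,2.4360454
42.875704,9.194451,2.6437812
44.911961,8.8733872,2.869262
47.044925,8.5640497,3.11399
49.279187,8.2660484,3.3795916
51.619559,7.9790046,3.6678258
54.071081,7.7025506,3.980599
56.63903,7.4363298,4.3199697
59.328936,7.1799965,4.6881671
62.146592,6.9332153,5.0875996
65.098064,6.6956611,5.5208698
68.189708,6.4670189,5.9907919
71.42818,6.2469834,6.500401
74.820455,6.035259,7.0529778
78.373835,5.8315593,7.6520593
82.095973,5.6356071,8.3014615
85.994883,5.4471341,9.0053008
90.078961,5.2658806,9.7680081
94.357,5.0915953,10.594363
98.838212,4.9240351,11.489504
103.53225,4.762965,12.458965
108.44921,4.6081577,13.508697
113.59969,4.4593934,14.64509
118.99478,4.3164599,15.875019
124.64609,4.1791518,17.205852
130.5658,4.0472708,18.645503
136.76664,3.9206255,20.20245
143.26197,3.7990309,21.885777
150.06579,3.6823084,23.705216
157.19273,3.5702854,25.671163
164.65814,3.4627957,27.794747
172.4781,3.3596785,30.087842
180.66945,3.2607789,32.563125
189.24982,3.1659473,35.234118
198.23769,3.0750396,38.115212
207.65241,2.9879167,41.221746
217.51426,2.9044443,44.570009
227.84447,2.8244934,48.177321
238.66528,2.7479392,52.062062
250,2.6746615,56.243708
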