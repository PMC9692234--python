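# synthetic Bethe-formula stopping table (Z/A=0.39575, I=823.0 eV); see scripts/generate_stopping_tables.py
energy_MeV,mass_stopping_power_MeV_cm2_g,csda_range_g_cm2
1,55.494039,0.018474492
1.0474921,55.507471,0.019330038
1.0972397,55.405989,0.02022695
1.1493499,55.199996,0.021169091
1.203935,54.899186,0.02216054
1.2611124,54.512587,0.023205622
1.3210052,54.048607,0.024308935
1.3837425,53.515066,0.025475385
1.4494594,52.919233,0.026710219
1.5182973,52.267864,0.028019055
1.5904044,51.567226,0.029407923
1.665936,50.823137,0.030883301
1.7450548,50.040983,0.032452153
1.8279311,49.225757,0.034121982
1.9147434,48.382072,0.035900863
2.0056786,47.514195,0.037797507
2.1009325,46.626061,0.039821309
2.2007102,45.721301,0.041982403
2.3052266,44.803257,0.044291743
2.4147066,43.875001,0.046761144
2.5293861,42.939356,0.049403383
2.649512,41.998909,0.052232267
2.7753428,41.056027,0.055262717
2.9071497,40.112873,0.058510882
3.0452164,39.171418,0.061994207
3.1898401,38.233457,0.065731589
3.3413323,37.300616,0.069743457
3.5000192,36.374368,0.074051927
3.6662424,35.456042,0.078680946
3.84036,34.546832,0.083656419
4.0227467,33.647808,0.089006425
4.2137954,32.759924,0.094761337
4.4139174,31.884028,0.10095408
4.6235436,31.020865,0.1076203
4.8431254,30.171091,0.11479861
5.0731356,29.335275,0.12253088
5.3140695,28.513908,0.13086243
5.5664458,27.707405,0.13984241
5.830808,26.916116,0.14952405
6.1077253,26.140329,0.15996507
6.397794,25.380273,0.17122806
6.7016387,24.636126,0.1833808
7.0199136,23.908016,0.19649684
7.3533041,23.196029,0.21065587
7.7025279,22.500207,0.22594433
8.0683371,21.820557,0.24245595
8.4515194,21.157053,0.26029231
8.8528998,20.509636,0.27956368
9.2733426,19.878221,0.30038952
9.7137531,19.262697,0.32289947
10.17508,18.66293,0.34723413
10.658316,18.078765,0.37354589
11.164501,17.51003,0.40200028
11.694727,16.956535,0.43277652
12.250134,16.418078,0.46606926
12.831919,15.894441,0.50208953
13.441334,15.385397,0.54106618
14.079691,14.890708,0.58324767
14.748365,14.410129,0.62890312
15.448796,13.943405,0.67832485
16.182491,13.490279,0.73182961
16.951032,13.050486,0.78976107
17.756072,12.623758,0.85249212
18.599345,12.209824,0.92042679
19.482667,11.808411,0.99400383
20.40794,11.419243,1.0736985
21.377156,11.042045,1.1600264
22.392402,10.676542,1.2535467
23.455864,10.322459,1.3548653
24.569832,9.9795201,1.4646401
25.736705,9.6474536,1.5835828
26.958995,9.3259883,1.7124661
28.239335,9.0148557,1.852127
29.58048,8.7137898,2.0034724
30.985319,8.4225274,2.1674859
32.456877,8.1408088,2.3452316
33.998322,7.8683776,2.5378642
35.612974,7.6049813,2.7466327
37.304309,7.3503711,2.9728907
39.075969,7.1043024,3.2181038
40.931769,6.8665347,3.4838578
42.875704,6.6368321,3.7718707
44.911961,6.4149627,4.0839996
47.044925,6.2006997,4.4222553
49.279187,5.9938204,4.7888123
51.619559,5.794107,5.1860209
54.071081,5.6013465,5.6164251
56.63903,5.4153304,6.08277
59.328936,5.235855,6.5880252
62.146592,5.0627215,7.1353967
65.098064,4.8957356,7.7283455
68.189708,4.734708,8.3706108
71.42818,4.5794538,9.0662217
74.820455,4.4297931,9.81953
78.373835,4.2855504,10.635223
82.095973,4.1465548,11.518354
85.994883,4.01264,12.47437
90.078961,3.8836443,13.509127
94.357,3.7594103,14.62894
98.838212,3.639785,15.840591
103.53225,3.5246196,17.151377
108.44921,3.4137698,18.569139
113.59969,3.3070952,20.102294
118.99478,3.2044596,21.759885
124.64609,3.105731,23.551599
130.5658,3.010781,25.487831
136.76664,2.9194852,27.57971
143.26197,2.8317233,29.83915
150.06579,2.7473782,32.278904
157.19273,2.6663367,34.912586
164.65814,2.5884892,37.75476
172.4781,2.5137294,40.820949
180.66945,2.4419545,44.127714
189.24982,2.373065,47.692707
198.23769,2.3069647,51.5347
207.65241,2.2435602,55.673682
217.51426,2.1827616,60.130866
227.84447,2.1244818,64.928788
238.66528,2.0686365,70.091344
250,2.0151444,75.64383
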