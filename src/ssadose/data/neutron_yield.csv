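# synthetic calibrated thick-target neutron yields (neutrons per stopped proton)
energy_MeV,tungsten,lead,brass,nickel
10,0.00047659694,0.00042893725,0.00038127755,0.00028604826
20,0.0020432158,0.0018388942,0.0016345727,0.0012274745
30,0.004787468,0.0043087212,0.0038299744,0.0028806258
40,0.008759458,0.0078835122,0.0070075664,0.0052821684
50,0.013995495,0.012595945,0.011196396,0.0084634382
60,0.020524325,0.018471892,0.01641946,0.012454269
70,0.028369856,0.025532871,0.022695885,0.017284697
80,0.037552618,0.033797356,0.030042095,0.022985894
90,0.048090636,0.043281572,0.038472509,0.029590741
100,0.06,0.054,0.048,0.037134216
110,0.07329526,0.065965734,0.058636208,0.045653664
120,0.087989706,0.079190735,0.070391765,0.055189007
130,0.10409558,0.093686022,0.083276464,0.065782897
140,0.12162424,0.10946181,0.097299389,0.077480846
150,0.14058627,0.12652764,0.11246901,0.090331326
160,0.1609916,0.14489244,0.12879328,0.10438586
170,0.18284959,0.16456463,0.14627967,0.11969908
180,0.20616907,0.18555216,0.16493526,0.13632881
190,0.23095843,0.20786258,0.18476674,0.15433611
200,0.25722563,0.23150307,0.2057805,0.17378533
210,0.28497829,0.25648046,0.22798263,0.19474414
220,0.31422366,0.28280129,0.25137893,0.21728358
230,0.34496871,0.31047184,0.27597497,0.2414781
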