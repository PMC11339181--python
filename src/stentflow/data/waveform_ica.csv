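t_frac,w
0.000,1.21529724
0.005,1.24748737
0.010,1.27999111
0.015,1.31267495
0.020,1.34540092
0.025,1.37802744
0.030,1.41041020
0.035,1.44240307
0.040,1.47385907
0.045,1.50463125
0.050,1.53457376
0.055,1.56354270
0.060,1.59139716
0.065,1.61800015
0.070,1.64321950
0.075,1.66692880
0.080,1.68900821
0.085,1.70934533
0.090,1.72783596
0.095,1.74438481
0.100,1.75890618
0.105,1.77132453
0.110,1.78157505
0.115,1.78960407
0.120,1.79536943
0.125,1.79884083
0.130,1.80000000
0.135,1.79884083
0.140,1.79536943
0.145,1.78960407
0.150,1.78157505
0.155,1.77132453
0.160,1.75890618
0.165,1.74438481
0.170,1.72783596
0.175,1.70934533
0.180,1.68900821
0.185,1.66692880
0.190,1.64321950
0.195,1.61800015
0.200,1.59139716
0.205,1.56354270
0.210,1.53457376
0.215,1.50463125
0.220,1.47385907
0.225,1.44240307
0.230,1.41041020
0.235,1.37802744
0.240,1.34540092
0.245,1.31267495
0.250,1.27999111
0.255,1.24748737
0.260,1.21529724
0.265,1.18354897
0.270,1.15236480
0.275,1.12186024
0.280,1.09214346
0.285,1.06331471
0.290,1.03546576
0.295,1.00867956
0.300,0.98302978
0.305,0.95858058
0.310,0.93538637
0.315,0.91349170
0.320,0.89293119
0.325,0.87372955
0.330,0.85590170
0.335,0.83945291
0.340,0.82437907
0.345,0.81066699
0.350,0.79829479
0.355,0.78723233
0.360,0.77744171
0.365,0.76887782
0.370,0.76148893
0.375,0.75521733
0.380,0.75000000
0.385,0.74576931
0.390,0.74245372
0.395,0.73997856
0.400,0.73826671
0.405,0.73723941
0.410,0.73681697
0.415,0.73691948
0.420,0.73746759
0.425,0.73838313
0.430,0.73958980
0.435,0.74101383
0.440,0.74258450
0.445,0.74423475
0.450,0.74590164
0.455,0.74752680
0.460,0.74905682
0.465,0.75044360
0.470,0.75164459
0.475,0.75262302
0.480,0.75334804
0.485,0.75379482
0.490,0.75394454
0.495,0.75378441
0.500,0.75330750
0.505,0.75251263
0.510,0.75140415
0.515,0.74999166
0.520,0.74828974
0.525,0.74631751
0.530,0.74409830
0.535,0.74165920
0.540,0.73903058
0.545,0.73624558
0.550,0.73333964
0.555,0.73034993
0.560,0.72731484
0.565,0.72427340
0.570,0.72126481
0.575,0.71832782
0.580,0.71550029
0.585,0.71281864
0.590,0.71031738
0.595,0.70802872
0.600,0.70598207
0.605,0.70420372
0.610,0.70271653
0.615,0.70153956
0.620,0.70068792
0.625,0.70017253
0.630,0.70000000
0.635,0.70017253
0.640,0.70068792
0.645,0.70153956
0.650,0.70271653
0.655,0.70420372
0.660,0.70598207
0.665,0.70802872
0.670,0.71031738
0.675,0.71281864
0.680,0.71550029
0.685,0.71832782
0.690,0.72126481
0.695,0.72427340
0.700,0.72731484
0.705,0.73034993
0.710,0.73333964
0.715,0.73624558
0.720,0.73903058
0.725,0.74165920
0.730,0.74409830
0.735,0.74631751
0.740,0.74828974
0.745,0.74999166
0.750,0.75140415
0.755,0.75251263
0.760,0.75330750
0.765,0.75378441
0.770,0.75394454
0.775,0.75379482
0.780,0.75334804
0.785,0.75262302
0.790,0.75164459
0.795,0.75044360
0.800,0.74905682
0.805,0.74752680
0.810,0.74590164
0.815,0.74423475
0.820,0.74258450
0.825,0.74101383
0.830,0.73958980
0.835,0.73838313
0.840,0.73746759
0.845,0.73691948
0.850,0.73681697
0.855,0.73723941
0.860,0.73826671
0.865,0.73997856
0.870,0.74245372
0.875,0.74576931
0.880,0.75000000
0.885,0.75521733
0.890,0.76148893
0.895,0.76887782
0.900,0.77744171
0.905,0.78723233
0.910,0.79829479
0.915,0.81066699
0.920,0.82437907
0.925,0.83945291
0.930,0.85590170
0.935,0.87372955
0.940,0.89293119
0.945,0.91349170
0.950,0.93538637
0.955,0.95858058
0.960,0.98302978
0.965,1.00867956
0.970,1.03546576
0.975,1.06331471
0.980,1.09214346
0.985,1.12186024
0.990,1.15236480
0.995,1.18354897
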