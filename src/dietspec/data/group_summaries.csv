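location,month,year,season,sex,min_prey_density,theoretical_min,n,mean_psi,use,shannon
BC,June,2012,Summer,Male,0.0110,0.2000,5,0.549,Yes,0.928
BC,June,2012,Summer,Female,0.0160,0.5000,2,0.680,No,1.236
BC,July,2012,Summer,Male,0.0002,0.1111,9,0.380,Yes,1.935
BC,July,2012,Summer,Female,0.2968,1.0000,1,0.000,No,0.608
BC,Aug,2012,Summer,Female,0.0001,0.0556,18,0.421,Yes,1.567
BC,Aug,2012,Summer,Male,0.0002,0.0588,17,0.390,Yes,1.618
BC,Sept,2012,Fall,Female,0.0124,0.0526,19,0.572,Yes,0.987
BC,Sept,2012,Fall,Male,0.0076,0.0833,12,0.427,Yes,1.600
BC,Aug,2013,Summer,Female,0.0139,0.2000,5,0.314,Yes,2.121
BC,Aug,2013,Summer,Male,0.0114,0.2000,5,0.478,Yes,1.145
BC,Sept,2013,Fall,Female,0.0103,0.0714,14,0.527,Yes,1.514
BC,Sept,2013,Fall,Male,0.0105,0.0769,13,0.487,Yes,1.403
BC,Oct,2013,Fall,Male,0.0107,0.0833,12,0.588,Yes,1.144
BC,Oct,2013,Fall,Female,0.0104,0.3333,3,0.614,No,0.884
BI,Apr,2016,Spring,Female,0.0120,0.1429,7,0.426,Yes,1.754
BI,Apr,2016,Spring,Male,0.0297,0.1429,7,0.387,Yes,1.169
BI,May,2016,Spring,Male,0.0094,0.0278,36,0.387,Yes,1.587
BI,May,2016,Spring,Female,0.0118,0.0370,27,0.305,Yes,1.751
BI,June,2016,Summer,Male,0.0122,0.0833,12,0.246,Yes,2.123
BI,June,2016,Summer,Female,0.0251,0.1250,8,0.214,Yes,1.942
BI,July,2016,Summer,Female,0.0477,0.1250,8,0.341,Yes,1.193
BI,July,2016,Summer,Male,0.2368,0.3333,3,0.529,No,0.879
CB,June,2012,Summer,Female,0.0006,0.1111,9,0.474,Yes,1.634
CB,June,2012,Summer,Male,0.0002,0.1429,7,0.344,Yes,1.717
CB,July,2012,Summer,Male,0.0003,0.0500,20,0.447,Yes,1.557
CB,July,2012,Summer,Female,0.0034,0.0625,16,0.395,Yes,2.115
CB,Aug,2012,Summer,Female,0.0002,0.1429,7,0.316,Yes,1.556
CB,Sept,2012,Fall,Female,0.0007,0.0526,19,0.313,Yes,1.846
CB,Sept,2012,Fall,Male,0.0029,0.1429,7,0.330,Yes,1.580
CB,Oct,2012,Fall,Male,0.0002,0.0625,16,0.263,Yes,2.059
CB,Oct,2012,Fall,Female,0.0004,0.0769,13,0.320,Yes,1.745
CB,Nov,2012,Fall,Male,0.0137,0.2500,4,0.988,No,0.063
CB,Nov,2012,Fall,Female,0.0110,0.5000,2,0.995,No,0.034
CB,Apr,2013,Spring,Female,0.0278,0.1000,10,0.352,Yes,1.705
CB,Apr,2013,Spring,Male,0.1160,1.0000,1,0.000,No,0.359
CB,May,2013,Spring,Female,0.0112,0.0909,11,0.313,Yes,1.979
CB,May,2013,Spring,Male,0.0123,0.2500,4,0.374,No,1.059
CB,June,2013,Summer,Female,0.0167,0.1111,9,0.489,Yes,1.337
CB,June,2013,Summer,Male,0.0154,0.3333,3,0.337,No,1.328
CB,July,2013,Summer,Female,0.0114,0.1250,8,0.400,Yes,1.610
CB,July,2013,Summer,Male,0.0116,0.1429,7,0.384,Yes,1.728
CB,Aug,2013,Summer,Female,0.0103,0.0667,15,0.228,Yes,2.147
CB,Aug,2013,Summer,Male,0.0143,0.2500,4,0.393,No,1.256
CB,Sept,2013,Fall,Female,0.0187,0.0833,12,0.327,Yes,1.687
CB,Sept,2013,Fall,Male,0.0108,0.1000,10,0.354,Yes,1.959
CB,Oct,2013,Fall,Female,0.0122,0.0833,12,0.546,Yes,1.313
CB,Oct,2013,Fall,Male,0.0103,0.1111,9,0.463,Yes,1.362
CB,Nov,2013,Fall,Male,0.0116,0.1250,8,0.531,Yes,0.932
CB,Nov,2013,Fall,Female,0.0110,0.1429,7,0.486,Yes,1.317
CB,May,2014,Spring,Male,0.0047,0.1000,10,0.222,Yes,1.911
CB,May,2014,Spring,Female,0.0126,0.1667,6,0.412,Yes,1.495
CB,June,2014,Summer,Male,0.0113,0.1250,8,0.365,Yes,1.509
CB,June,2014,Summer,Female,0.0105,0.1667,6,0.349,Yes,1.542
CB,July,2014,Summer,Male,1.0000,1.0000,1,0.000,No,0.000
CB,Aug,2014,Summer,Male,0.0008,0.3333,3,0.341,No,1.572
CB,Aug,2014,Summer,Female,0.0200,0.5000,2,0.600,No,1.292
CB,Sept,2014,Fall,Male,0.0139,0.1111,9,0.256,Yes,1.729
CB,Sept,2014,Fall,Female,0.0007,0.1250,8,0.601,Yes,1.127
CB,Oct,2014,Fall,Male,0.0024,0.0270,37,0.265,Yes,2.048
CB,Oct,2014,Fall,Female,0.0104,0.0417,24,0.225,Yes,2.230
CB,Nov,2014,Fall,Male,0.0003,0.0435,23,0.249,Yes,1.820
CB,Nov,2014,Fall,Female,1.0000,1.0000,1,0.000,No,0.000
CM,May,2012,Spring,Male,0.0001,0.0667,15,0.570,Yes,1.568
CM,May,2012,Spring,Female,0.0144,0.2500,4,0.586,No,0.993
CM,June,2012,Summer,Male,0.0017,0.0556,18,0.295,Yes,2.150
CM,June,2012,Summer,Female,0.0007,0.0909,11,0.338,Yes,2.362
CM,July,2012,Summer,Male,0.0004,0.0455,22,0.269,Yes,2.357
CM,Aug,2012,Summer,Male,0.0012,0.0909,11,0.272,Yes,1.945
CM,Aug,2012,Summer,Female,0.0008,0.1111,9,0.232,Yes,2.216
CM,Sept,2012,Fall,Female,0.0105,0.0500,20,0.240,Yes,2.200
CM,Sept,2012,Fall,Male,0.0019,0.1000,10,0.268,Yes,1.986
CM,Oct,2012,Fall,Female,0.0000,0.0625,16,0.251,Yes,1.814
CM,Oct,2012,Fall,Male,0.0000,0.1250,8,0.575,Yes,0.691
CM,Apr,2013,Spring,Male,0.0015,0.0769,13,0.317,Yes,1.560
CM,Apr,2013,Spring,Female,0.0120,0.2500,4,0.304,No,1.761
CM,May,2013,Spring,Female,0.0116,0.0833,12,0.213,Yes,2.219
CM,May,2013,Spring,Male,0.0144,0.2000,5,0.292,Yes,1.334
CM,June,2013,Summer,Male,0.0105,0.1250,8,0.206,Yes,1.901
CM,June,2013,Summer,Female,0.0179,0.2000,5,0.361,Yes,1.455
CM,July,2013,Summer,Male,0.0135,0.0909,11,0.600,Yes,1.203
CM,July,2013,Summer,Female,0.0220,0.1429,7,0.540,Yes,0.985
CM,Aug,2013,Summer,Female,0.0135,0.1000,10,0.275,Yes,2.141
CM,Aug,2013,Summer,Male,0.0125,0.1000,10,0.423,Yes,1.615
CM,Sept,2013,Fall,Female,0.0112,0.0625,16,0.256,Yes,1.995
CM,Sept,2013,Fall,Male,0.0133,0.1111,9,0.506,Yes,1.296
CM,Oct,2013,Fall,Female,0.0120,0.0909,11,0.328,Yes,1.778
CM,Oct,2013,Fall,Male,0.0111,0.1429,7,0.463,Yes,1.333
FR,May,2012,Spring,Male,0.0025,0.0769,13,0.302,Yes,2.388
FR,June,2012,Summer,Male,0.0055,0.0588,17,0.372,Yes,2.479
FR,June,2012,Summer,Female,0.0005,0.3333,3,0.574,No,1.865
FR,July,2012,Summer,Male,0.0101,0.0476,21,0.771,Yes,0.728
FR,July,2012,Summer,Female,0.0118,0.5000,2,0.585,No,1.341
FR,Aug,2012,Summer,Male,0.0105,0.1667,6,0.974,Yes,0.127
FR,Aug,2012,Summer,Female,0.0130,0.5000,2,0.976,No,0.140
FR,Sept,2012,Fall,Male,0.0102,0.0345,29,0.388,Yes,1.310
FR,Sept,2012,Fall,Female,0.0016,0.0769,13,0.206,Yes,2.020
FR,Oct,2012,Fall,Male,0.0110,0.0769,13,0.976,Yes,0.092
FR,Oct,2012,Fall,Female,0.0124,0.2000,5,0.648,Yes,0.701
FR,Apr,2013,Spring,Male,0.0110,0.1111,9,0.523,Yes,0.955
FR,Apr,2013,Spring,Female,0.0108,0.2000,5,0.463,Yes,1.190
FR,May,2013,Spring,Male,0.0152,0.0667,15,0.246,Yes,2.325
FR,May,2013,Spring,Female,0.0123,0.2500,4,0.373,No,1.413
FR,June,2013,Summer,Male,0.0135,0.3333,3,0.361,No,1.623
FR,June,2013,Summer,Female,0.0107,1.0000,1,0.000,No,0.059
FR,Aug,2013,Summer,Male,1.0000,0.5000,2,1.000,No,0.000
FR,July,2013,Summer,Male,0.0118,0.2000,5,0.269,Yes,1.808
FR,July,2013,Summer,Female,0.0455,1.0000,1,0.000,No,1.679
FR,Aug,2013,Summer,Female,0.0119,0.3333,3,0.420,No,1.483
FR,Sept,2013,Fall,Female,0.0112,0.1429,7,0.811,Yes,0.626
FR,Oct,2013,Fall,Male,0.0105,0.0833,12,0.772,Yes,0.731
FR,Oct,2013,Fall,Female,0.0047,0.2000,5,0.562,Yes,1.316
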