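rsid,effect_allele,other_allele,beta,maf
rs56414379,T,G,2.095,0.439
rs8598520,G,T,0.624,0.482
rs4778298,G,C,1.19,0.417
rs81946657,A,T,3.185,0.315
rs51503999,A,T,2.2,0.059
rs55956357,T,A,2.218,0.308
rs78303927,A,G,3.236,0.087
rs30417505,G,C,0.82,0.056
rs91903126,C,A,2.232,0.251
rs4994031,C,A,1.031,0.289
rs57237402,T,A,2.8,0.279
rs69236100,T,A,6.425,0.199
rs42194520,C,A,3.696,0.382
rs75036721,G,T,3.453,0.175
rs27115640,G,T,2.571,0.233
rs2746091,C,G,1.197,0.252
rs17540258,A,T,1.654,0.23
rs75777319,G,T,1.986,0.253
rs83434037,G,A,1.417,0.116
rs6186432,A,C,1.658,0.457
rs49080464,G,A,5.3,0.227
rs51449741,C,A,6.409,0.371
rs82349538,T,G,2.638,0.271
rs24171944,G,A,4.794,0.23
rs51986452,G,A,4.134,0.288
rs21619864,A,T,3.374,0.488
rs32817017,A,T,1.66,0.467
rs86881328,G,T,1.936,0.369
rs73666373,G,T,0.763,0.387
rs24061409,A,G,6.806,0.461
rs58281037,T,A,5.92,0.353
rs84156872,C,T,5.401,0.106
rs78475331,T,A,2.514,0.456
rs22334096,T,A,5.983,0.14
rs98864828,A,T,2.726,0.328
rs87263406,A,T,7.345,0.289
rs75639161,A,C,3.803,0.165
rs73319865,A,T,2.353,0.064
rs69084477,C,G,3.736,0.295
rs65006277,G,A,3.115,0.455
rs75520345,T,G,2.68,0.497
rs41613714,A,C,2.887,0.168
rs58112434,A,G,1.827,0.056
rs57706656,T,G,2.211,0.245
rs71922258,T,G,2.777,0.35
rs13061513,C,T,2.717,0.229
rs6499019,G,A,2.508,0.125
rs42525804,C,A,2.658,0.348
rs96338256,A,T,1.736,0.32
rs229009,A,C,4.957,0.111
rs44728598,C,T,1.367,0.22
rs55939366,C,G,3.522,0.18
rs22235688,T,C,3.403,0.085
rs88553084,C,G,1.869,0.144
rs65163359,T,C,1.605,0.099
rs71628318,C,A,2.179,0.247
rs5306317,C,G,2.542,0.344
rs33416541,G,T,4.0,0.099
rs68770834,T,C,1.828,0.057
rs42630430,G,A,5.136,0.317
rs1023504,G,A,1.902,0.079
rs82188408,T,A,3.907,0.196
rs18297004,G,T,2.438,0.382
rs17905417,C,G,2.344,0.173
rs62068598,A,T,2.306,0.385
rs45986387,C,T,5.193,0.494
rs39745090,G,A,1.786,0.455
rs17267697,C,T,4.068,0.351
rs72307324,C,A,2.237,0.359
rs67213824,A,G,1.056,0.079
rs24401674,G,T,8.158,0.447
rs50172547,C,T,2.818,0.172
rs83788278,G,A,1.682,0.277
rs63797436,A,C,0.531,0.49
rs15227279,A,G,7.69,0.1
rs81932057,T,C,2.251,0.49
rs39961589,C,T,2.481,0.087
rs77850338,T,G,8.605,0.488
rs97707359,A,T,1.646,0.053
rs28261838,G,T,2.394,0.219
rs3341978,T,C,3.469,0.29
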