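genotype,group,lignin_pct,hemicellulose_pct,cellulose_pct,lignin_yield,hemicellulose_yield,cellulose_yield,ethanol_yield
PARL 792,mariola,16.57,15.84,28.66,3131,3026,5418,5191
PARL 798,mariola,17.09,15.2,29.87,2627,2385,4618,4288
PARL 799,mariola,15.84,16.78,33.46,4008,4305,8194,7363
PARL 800,mariola,16.23,17.32,33.25,3730,3862,7212,6595
PARL 815,mariola,16.3,16.33,32.29,3806,3910,7459,6758
PARL 818,mariola,14.43,17.28,33.85,3643,4282,8082,7143
PI 478657,guayule_hybrid,17.12,15.4,21.34,3268,3024,4644,4901
PI 599675,guayule_hybrid,14.86,14.89,21.39,6874,7288,10248,10982
PI 599676,guayule_hybrid,14.87,14.11,22.36,4867,4785,7731,7841
PI 478666,guayule_hybrid,12.58,15.54,22.58,2987,3767,5667,5595
PI 478667,guayule_hybrid,12.3,13.57,24.15,3185,3651,6464,5999
W6 551,guayule_hybrid,13.83,16.77,25.64,5506,6637,10437,10113
W6 2271,guayule_hybrid,15.5,14.03,20.32,5897,5538,8069,8822
W6 2189,guayule_hybrid,17.46,17.21,24.57,4085,3985,6218,6371
W6 2272,guayule,15.63,15.29,20.68,4063,4040,5640,6201
W6 2196,guayule,15,13.81,18.85,2779,2656,4012,4290
W6 2244,guayule,15.97,16.05,20.78,2508,2454,3946,4025
W6 2245,guayule,16.24,15.1,19.82,2021,1852,3240,3197
W6 2248,guayule,15.94,16.89,24.69,3631,3874,6065,6079
W6 2260,guayule,17.25,16.03,22.02,3348,3154,5004,5163
PARL 805,guayule,16.4,15.46,20.46,3045,2881,4215,4573
PARL 816,guayule,16.51,15.03,20.7,2504,2310,3845,3907
PARL 820,guayule,14.87,13.93,19.83,2847,2704,4409,4515
PI 478639,guayule,18.01,15.98,23.38,2928,2696,4484,4528
PI 478640,guayule,16.92,16,22.08,2593,2466,3776,3989
PI 478642,guayule,18.48,15.5,19.36,2511,2212,3597,3726
PI 478643,guayule,17.35,16.41,23.24,5450,5407,7827,8379
PI 478644,guayule,14.97,14.41,19.16,2760,2658,4076,4273
PI 478649,guayule,16.89,15.67,18.67,2950,2818,4235,4509
PI 478653,guayule,17.96,14.83,18.37,2874,2492,3741,4088
PI 478654,guayule,21.31,16.23,21.99,3212,2670,4379,4590
PI 478655,guayule,16.71,16.11,21.43,3462,3360,4985,5290
PI 478656,guayule,16.93,15.44,19.38,2650,2440,3861,4027
PI 478659,guayule,15.29,14.92,20.84,2608,2480,4066,4120
PI 478665,guayule,13.27,15.94,23.75,2480,3031,4638,4573
W6 7157,guayule,15.63,15.29,20.68,4063,4040,5640,6201
PI 599674,guayule,15.78,14.62,20.1,3406,3221,5076,5281
PI 599677,guayule,15.79,15.23,19.73,2934,2708,3538,4157
PI 599678,guayule,17.16,16.97,19.35,2206,2210,2513,3121
PI 599679,guayule,15.88,15.57,20.37,3116,3078,4155,4663
PARL 912,guayule,18.97,15.34,19.87,2697,2307,3838,3968
PARL 917,guayule,18.16,16.68,22.7,3936,3728,5665,5997
PARL 920,guayule,16.16,14.97,20.89,2406,2235,3659,3084
PARL 922,guayule,16.68,15.83,21.42,4106,3929,5932,6285
PARL 924,guayule,15.39,16.38,23.25,2840,2873,4634,4643
PARL 927,guayule,15.15,14.96,19.74,2516,2441,3933,4005
PARL 929,guayule,15.4,14.87,18.3,2694,2592,3848,4112
PARL 930,guayule,18,15.59,23.99,3082,2782,4550,4670
PARL 931,guayule,17.96,16.13,22.88,4937,4744,7178,7560
PARL 932,guayule,17.55,15.89,22.19,2898,2685,4232,4408
PARL 933,guayule,15.62,13.69,17.86,2866,2653,4016,4299
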