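genotype,group,YSI_lignin_yield,YSI_hemicellulose_yield,YSI_cellulose_yield,YSI_ethanol_yield,YI_lignin_yield,YI_hemicellulose_yield,YI_cellulose_yield,YI_ethanol_yield,STI_lignin_yield,STI_hemicellulose_yield,STI_cellulose_yield,STI_ethanol_yield
PARL 792,mariola,0.21,0.13,0.22,0.20,0.73,0.60,0.98,0.81,0.24,0.15,0.29,0.24
PARL 798,mariola,0.33,0.21,0.35,0.31,0.82,0.68,1.14,0.91,0.20,0.12,0.24,0.19
PARL 799,mariola,0.35,0.28,0.35,0.33,1.39,1.61,2.19,1.76,0.53,0.49,0.89,0.66
PARL 800,mariola,0.50,0.46,0.55,0.51,1.51,1.90,2.32,1.91,0.44,0.41,0.64,0.51
PARL 815,mariola,0.12,0.05,0.11,0.10,0.52,0.32,0.74,0.56,0.22,0.10,0.32,0.22
PARL 818,mariola,0.42,0.37,0.41,0.40,1.45,1.98,2.40,1.96,0.48,0.56,0.92,0.68
PI 478657,guayule_hybrid,0.35,0.22,0.25,0.27,1.09,0.89,0.88,0.95,0.33,0.19,0.20,0.24
PI 599675,guayule_hybrid,0.21,0.16,0.19,0.19,1.50,1.61,1.58,1.57,1.04,0.88,0.85,0.94
PI 599676,guayule_hybrid,0.34,0.28,0.30,0.31,1.48,1.58,1.55,1.55,0.61,0.48,0.53,0.56
PI 478666,guayule_hybrid,0.10,0.03,0.08,0.08,0.40,0.18,0.51,0.42,0.15,0.06,0.20,0.16
PI 478667,guayule_hybrid,0.33,0.30,0.26,0.39,1.02,1.54,1.24,1.25,0.30,0.42,0.39,0.28
W6 551,guayule_hybrid,0.33,0.29,0.26,0.29,1.70,2.45,2.07,2.04,0.85,1.09,1.08,1.03
W6 2271,guayule_hybrid,0.42,0.40,0.35,0.39,2.24,2.61,2.06,2.27,1.16,0.90,0.79,0.95
W6 2189,guayule_hybrid,0.19,0.15,0.16,0.17,0.85,0.87,0.85,0.86,0.36,0.27,0.29,0.31
W6 2272,guayule,0.48,0.48,0.45,0.47,1.75,2.25,1.80,1.90,0.61,0.55,0.47,0.55
W6 2196,guayule,0.12,0.02,0.08,0.08,0.39,0.08,0.31,0.30,0.12,0.02,0.08,0.08
W6 2244,guayule,0.33,0.20,0.24,0.26,0.72,0.60,0.64,0.66,0.15,0.10,0.11,0.12
W6 2245,guayule,0.19,0.03,0.12,0.11,0.37,0.07,0.27,0.25,0.07,0.01,0.04,0.04
W6 2248,guayule,0.35,0.26,0.26,0.29,1.21,1.33,1.21,1.25,0.40,0.36,0.37,0.39
W6 2260,guayule,0.41,0.28,0.26,0.31,1.12,1.01,0.84,0.98,0.29,0.20,0.18,0.22
PARL 805,guayule,0.36,0.27,0.24,0.28,1.08,1.03,0.81,0.95,0.31,0.21,0.18,0.23
PARL 816,guayule,0.36,0.24,0.31,0.31,0.78,0.68,0.78,0.76,0.17,0.10,0.13,0.14
PARL 820,guayule,0.23,0.14,0.21,0.20,0.63,0.50,0.65,0.63,0.16,0.09,0.13,0.14
PI 478639,guayule,0.31,0.14,0.19,0.21,0.83,0.51,0.61,0.65,0.22,0.10,0.13,0.15
PI 478640,guayule,0.25,0.15,0.21,0.22,0.69,0.56,0.66,0.66,0.19,0.11,0.14,0.14
PI 478642,guayule,0.23,0.09,0.13,0.15,0.55,0.26,0.34,0.39,0.13,0.04,0.06,0.07
PI 478643,guayule,0.37,0.26,0.24,0.28,1.96,1.88,1.53,1.74,1.00,0.72,0.64,0.77
PI 478644,guayule,0.27,0.17,0.21,0.22,0.75,0.62,0.67,0.70,0.20,0.12,0.14,0.16
PI 478649,guayule,0.25,0.11,0.14,0.16,0.69,0.43,0.43,0.52,0.18,0.09,0.09,0.12
PI 478653,guayule,0.34,0.23,0.24,0.27,0.94,0.76,0.67,0.79,0.25,0.13,0.13,0.16
PI 478654,guayule,0.27,0.13,0.19,0.20,0.78,0.45,0.55,0.60,0.21,0.08,0.11,0.13
PI 478655,guayule,0.29,0.22,0.23,0.25,1.00,0.99,0.91,0.96,0.33,0.24,0.23,0.27
PI 478656,guayule,0.30,0.16,0.19,0.21,0.73,0.51,0.50,0.58,0.17,0.09,0.09,0.11
PI 478659,guayule,0.31,0.21,0.27,0.27,0.74,0.68,0.74,0.73,0.17,0.11,0.14,0.14
PI 478665,guayule,0.53,0.47,0.40,0.45,1.14,1.67,1.36,1.37,0.24,0.31,0.30,0.29
W6 7157,guayule,0.48,0.48,0.45,0.47,1.75,2.25,1.80,1.90,0.61,0.55,0.47,0.55
PI 599674,guayule,0.42,0.35,0.36,0.37,1.14,1.18,1.07,1.12,0.29,0.22,0.21,0.24
PI 599677,guayule,0.48,0.54,0.55,0.53,1.25,1.62,1.30,1.37,0.32,0.26,0.20,0.26
PI 599678,guayule,0.51,0.50,0.49,0.50,0.99,1.26,0.85,1.00,0.19,0.17,0.10,0.14
PI 599679,guayule,0.47,0.46,0.41,0.45,1.32,1.65,1.22,1.36,0.35,0.31,0.24,0.30
PARL 912,guayule,0.19,0.06,0.16,0.14,0.47,0.20,0.39,0.37,0.11,0.03,0.06,0.07
PARL 917,guayule,0.38,0.30,0.30,0.33,1.32,1.34,1.16,1.25,0.44,0.31,0.29,0.35
PARL 920,guayule,0.16,0.06,0.15,0.09,0.43,0.21,0.43,0.27,0.11,0.04,0.08,0.06
PARL 922,guayule,0.32,0.29,0.30,0.31,1.15,1.30,1.15,1.19,0.40,0.31,0.29,0.33
PARL 924,guayule,0.25,0.17,0.22,0.21,0.67,0.65,0.73,0.70,0.18,0.13,0.16,0.16
PARL 927,guayule,0.26,0.11,0.17,0.18,0.62,0.38,0.47,0.50,0.14,0.07,0.09,0.10
PARL 929,guayule,0.37,0.23,0.24,0.28,0.92,0.78,0.69,0.79,0.22,0.14,0.13,0.16
PARL 930,guayule,0.24,0.13,0.19,0.19,0.76,0.50,0.68,0.66,0.23,0.10,0.16,0.16
PARL 931,guayule,0.21,0.12,0.16,0.16,1.01,0.78,0.84,0.88,0.47,0.27,0.30,0.34
PARL 932,guayule,0.29,0.19,0.27,0.25,0.83,0.71,0.84,0.81,0.23,0.14,0.17,0.18
PARL 933,guayule,0.30,0.14,0.19,0.21,0.84,0.54,0.59,0.67,0.23,0.11,0.12,0.16
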