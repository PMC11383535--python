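participant,valid_trials,hits,adjusted_hits,mean_new,se_new,t,p,flagged
1,266,172,172,1.74,0.076,-3.419,0.001,False
2,261,166,130,2.51,0.111,4.576,0.000,True
3,280,151,151,1.91,0.071,-1.264,0.209,False
4,261,231,198,2.28,0.083,3.375,0.001,True
5,296,228,115,2.50,0.061,8.179,0.000,True
6,276,165,92,2.27,0.080,3.366,0.001,True
7,276,210,210,1.75,0.115,-2.175,0.032,False
8,291,281,206,2.51,0.086,5.940,0.000,True
9,294,206,206,2.05,0.072,0.698,0.487,False
10,274,241,196,2.30,0.107,2.808,0.006,True
11,269,222,207,2.33,0.116,2.835,0.006,True
12,259,180,96,2.41,0.064,6.435,0.000,True
13,250,208,158,2.66,0.132,5.001,0.000,True
14,249,188,188,2.10,0.058,1.732,0.086,False
15,234,141,141,1.80,0.115,-1.745,0.084,False
16,279,227,181,2.84,0.109,7.712,0.000,True
17,257,184,184,1.71,0.113,-2.565,0.012,False
18,276,210,148,2.83,0.089,9.344,0.000,True
19,248,166,166,2.02,0.134,0.149,0.882,False
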