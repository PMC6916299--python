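study_id,year,estimate,variance,n_treat,n_control
1,1998,1.425,0.2814,10,8
2,2003,1.068,0.1016,22,23
3,1993,0.924,0.0727,29,32
4,1993,0.909,0.0725,29,32
5,2005,0.281,0.1355,23,11
6,2005,1.646,0.1307,21,20
7,1997,1.007,0.1556,15,14
8,2002,0.996,0.0374,55,66
9,2002,0.731,0.0355,55,66
10,1998,1.882,0.2752,11,10
11,2000,1.082,0.1596,13,16
12,1997,2.326,0.3725,9,9
13,1994,-0.229,0.3355,6,6
14,1980,0.191,0.2009,10,10
15,2001,0.980,0.0953,18,33
16,2001,1.620,0.1196,16,33
17,2005,2.997,0.4745,10,8
18,1999,0.860,0.3642,6,6
19,2006,1.494,0.2558,10,10
20,2003,0.597,0.1644,11,15
21,1998,0.674,0.1216,19,16
22,1998,0.490,0.1186,19,16
23,2004,3.780,0.7541,6,9
24,2004,1.590,0.2776,10,9
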