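from,to,set,ddg_raw,se_raw,ddg_cc,se_cc,ddg_corr,se_corr,ddg_exp,charge_change
17,45,1,-4.6,0.2,,,-4.6,0.2,10.6,0
17,49,1,8.5,0.2,,,8.5,0.2,14.3,0
17,91,1,16.7,0.3,,,16.7,0.3,10.7,0
45,91,1,11.4,0.4,,,11.4,0.4,0.1,0
46,49,1,-0.3,0.1,,,-0.3,0.1,1.4,0
47,91,1,-3.3,0.3,,,-3.3,0.3,1.0,0
48,91,1,6.0,0.4,,,6.0,0.4,-3.6,0
49,91,1,1.5,0.3,,,1.5,0.3,-3.6,0
93,91,1,5.7,0.1,,,5.7,0.1,-1.3,0
95,91,1,-1.0,0.3,,,-1.0,0.3,-0.2,0
96,46,1,2.5,0.3,,,2.5,0.3,0.2,0
96,91,1,7.4,0.3,,,7.4,0.3,-2.0,0
96,98,1,2.5,0.2,,,2.5,0.2,-4.4,0
98,46,1,4.3,0.2,,,4.3,0.2,4.6,0
98,91,1,9.8,0.3,,,9.8,0.3,2.4,0
99,91,1,2.4,0.2,,,2.4,0.2,-3.6,0
100,91,1,3.4,0.4,,,3.4,0.4,1.3,0
101,91,1,-4.5,0.6,8.4,0.3,3.9,0.7,0.2,1
102,91,1,17.4,0.4,,,17.4,0.4,0.0,0
10,73,2,-17.4,0.5,6.9,0.2,-10.5,0.6,2.0,1
10,79,2,11.7,0.5,,,11.7,0.5,-0.9,0
12,76,2,6.9,0.2,,,6.9,0.2,19.4,0
38,10,2,7.1,0.4,-7.9,0.3,-0.8,0.5,-8.5,1
41,12,2,7.2,0.4,-6.9,0.2,0.4,0.5,-21.9,1
41,38,2,5.2,0.2,,,5.2,0.2,0.0,0
41,M1,2,2.1,0.2,,,2.1,0.2,,0
73,75,2,11.5,0.2,,,11.5,0.2,6.4,0
74,76,2,5.4,0.2,,,5.4,0.2,12.2,0
76,10,2,2.3,0.2,,,2.3,0.2,-5.9,0
77,12,2,11.2,0.1,,,11.2,0.1,-4.3,0
77,82,2,5.5,0.2,,,5.5,0.2,-1.0,0
78,12,2,-0.8,0.2,,,-0.8,0.2,2.1,0
81,85,2,11.5,0.3,,,11.5,0.3,-6.5,0
82,84,2,8.8,0.2,,,8.8,0.2,9.5,0
83,12,2,0.8,0.2,,,0.8,0.2,-5.1,0
84,76,2,3.4,0.1,,,3.4,0.1,6.5,0
85,76,2,3.2,0.1,,,3.2,0.1,14.6,0
88,76,2,5.7,0.2,,,5.7,0.2,12.8,0
88,85,2,-2.0,0.3,,,-2.0,0.3,-1.8,0
89,76,2,5.1,0.2,,,5.1,0.2,11.9,0
M1,84,2,9.7,0.4,-6.8,0.2,2.9,0.5,,1
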