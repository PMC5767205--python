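ligand,XP,SP,AD4,Vina,QPLD,CS,CS_rank,CR_rank,RMSD
1,-35.6,-32.6,-38.2,-36.8,-38.7,-36.4,53,70,7.7
2,-24.0,-33.3,-36.9,-37.7,-37.0,-33.8,71,79,7.4
3,-35.8,-33.7,-42.6,-45.2,-41.2,-39.7,46,50,6.4
4,-37.1,-26.8,-45.0,-39.7,-40.9,-37.9,50,54,7.0
5,-37.5,-31.7,-33.6,-35.1,-38.6,-35.3,59,73,7.3
6,-49.2,-43.7,-48.2,-50.2,-49.0,-48.1,14,13,6.7
7,-55.9,-49.0,-53.5,-55.6,-58.6,-54.5,1,1,1.2
8,-47.5,-42.6,-42.8,-51.5,-39.0,-44.7,29,35,6.5
9,-36.1,-41.2,-49.1,-54.8,-40.0,-44.2,30,33,6.9
10,-33.8,-33.6,-25.0,-26.8,-38.6,-31.6,80,92,3.3
11,-26.3,-31.6,-26.0,-22.2,-37.6,-28.7,89,99,9.4
12,-10.0,-35.7,-26.3,-24.7,-41.0,-27.5,92,83,3.4
13,-41.8,-45.4,-52.5,-58.6,-41.7,-48.0,15,11,1.3
14,-36.9,-42.8,-47.2,-53.1,-38.8,-43.8,35,40,6.5
15,-43.3,-26.8,-42.3,-38.9,-40.6,-38.4,48,52,6.3
16,-29.9,-26.5,-32.3,-29.3,-16.7,-26.9,95,95,6.0
17,-39.4,-37.2,-32.4,-24.7,-41.6,-35.1,63,59,6.2
18,-51.0,-36.9,-39.2,-44.8,-41.5,-42.7,41,38,9.3
19,-51.0,-42.9,-48.1,-51.5,-54.6,-49.6,10,12,1.3
20,-56.1,-44.2,-49.0,-50.2,-59.1,-51.7,5,6,1.2
21,-54.7,-44.0,-46.9,-55.2,-56.6,-51.5,6,5,1.2
22,-52.2,-41.6,-45.9,-50.2,-54.2,-48.8,11,14,1.7
23,-46.7,-38.5,-47.1,-42.3,-41.7,-43.3,39,30,4.5
24,-52.8,-46.7,-46.4,-57.3,-56.6,-52.0,4,3,1.6
25,-56.2,-41.3,-49.9,-56.5,-59.2,-52.6,2,2,1.2
26,-54.1,-39.3,-50.0,-53.6,-56.3,-50.7,9,9,1.4
27,-54.9,-52.0,-39.7,-51.5,-40.3,-47.7,18,18,1.3
28,-55.9,-50.2,-42.8,-54.4,-40.3,-48.7,12,10,1.1
29,-55.4,-48.6,-42.0,-53.6,-40.4,-48.0,16,15,1.4
30,-38.7,-45.4,-34.5,-44.8,-40.0,-40.7,45,49,2.0
31,-51.5,-48.3,-45.7,-49.4,-41.6,-47.3,19,15,1.8
32,-56.7,-43.0,-38.8,-40.2,-56.1,-47.0,21,20,1.4
33,-35.5,-16.7,-39.4,-23.8,-40.7,-31.2,82,71,
34,-16.7,-17.4,-22.6,-25.9,-16.7,-19.9,101,101,9.6
35,-40.4,-47.1,-34.4,-43.5,-41.1,-41.3,44,43,2.5
36,-55.8,-53.8,-20.1,-42.7,-40.0,-42.5,42,41,1.8
37,-41.1,-41.0,-41.7,-43.5,-41.0,-41.7,43,42,
38,-37.2,-23.8,-34.7,-26.8,-41.8,-32.8,75,62,
39,-45.5,-43.8,-47.3,-54.0,-39.2,-46.0,24,23,
40,-49.0,-40.8,-43.8,-53.1,-38.1,-45.0,28,37,
41,-40.3,-35.4,-29.9,-23.4,-39.0,-33.6,73,77,
42,-47.9,-40.3,-37.6,-53.1,-41.8,-44.1,31,26,
43,-36.7,-23.2,-41.2,-37.2,-39.8,-35.6,58,60,
44,-52.1,-41.6,-42.4,-41.8,-41.0,-43.8,33,29,
45,-16.7,-16.7,-33.1,-15.9,-36.4,-23.8,98,100,
46,-38.7,-37.7,-38.7,-23.8,-41.0,-36.0,55,56,
47,-39.6,-36.6,-40.1,-31.4,-41.8,-37.9,51,48,
48,-43.8,-36.7,-32.4,-25.1,-41.0,-35.8,57,57,
49,-40.0,-35.8,-38.5,-21.8,-38.0,-34.8,64,72,
50,-52.0,-41.5,-42.0,-48.1,-51.8,-47.1,20,21,
51,-55.4,-39.9,-49.3,-52.3,-59.6,-51.3,7,8,
52,-53.3,-49.2,-48.7,-51.5,-58.3,-52.2,3,4,
53,-49.7,-50.3,-37.4,-52.3,-40.0,-45.9,25,27,
54,-53.4,-47.3,-45.4,-54.0,-53.7,-50.8,8,7,
55,-51.6,-43.1,-47.1,-51.0,-39.7,-46.5,22,22,
56,-58.5,-41.5,41.4,-32.2,-62.9,-30.7,84,39,
57,-47.4,-41.0,-44.6,-48.5,-16.7,-39.7,47,46,
58,-57.6,-51.4,-37.9,-52.7,-16.7,-43.3,37,28,
59,-48.2,-44.9,-29.2,-47.7,-16.7,-37.3,52,53,
60,-56.5,-49.5,-42.8,-52.7,-39.5,-48.2,13,17,
61,-43.6,-49.3,-40.9,-53.1,-38.5,-45.1,27,33,
62,-43.5,-49.0,-39.4,-51.0,-56.2,-47.8,17,19,
63,-44.1,-49.6,-33.5,-52.3,-40.8,-44.0,32,31,
64,-49.9,-47.2,-34.4,-45.6,-39.2,-43.3,37,44,
65,-9.2,-16.7,-42.2,-24.7,-16.7,-21.9,100,93,
66,-50.7,-43.3,-37.9,-44.8,-40.7,-43.5,36,36,
67,-42.2,-43.0,-11.8,-35.1,-41.0,-34.6,65,55,
68,-49.9,-47.2,-33.2,-45.6,-39.2,-43.0,40,45,
69,-40.9,-51.6,-15.8,-40.6,-41.3,-38.0,49,47,
70,-52.0,-39.0,-49.5,-52.3,-39.7,-46.5,23,23,
71,-43.9,-44.2,-39.2,-49.8,-41.8,-43.8,34,25,
72,-55.4,-50.0,-36.9,-48.1,-39.2,-45.9,26,32,
73,-34.0,-36.6,-36.3,-28.0,-40.5,-35.1,62,65,
74,-38.1,-39.2,-26.7,-21.8,-39.0,-33.0,74,75,
75,-24.8,-33.3,-35.8,-29.3,-37.8,-32.2,79,87,
76,-39.2,-35.9,-28.4,-27.6,-41.2,-34.4,67,60,
77,-32.5,-16.7,-24.5,-25.9,-38.9,-27.7,91,97,
78,-34.9,-37.1,-20.3,-14.2,-36.4,-28.6,90,96,
79,-21.7,-37.2,-29.5,-28.5,-16.7,-26.7,96,90,
80,-41.4,-33.6,-31.1,-26.4,-16.7,-29.8,86,79,
81,-37.0,-24.8,-26.0,-24.3,-39.7,-30.4,85,89,
82,-40.9,-38.5,-23.0,-26.4,-41.8,-34.1,68,57,
83,-27.3,-39.1,-27.2,-20.5,-39.7,-30.8,83,86,
84,-36.2,-38.1,-25.6,-28.0,-40.9,-33.8,72,66,
85,-14.6,-36.1,-29.9,-27.6,-40.4,-29.7,88,76,
86,-16.7,-16.7,-13.2,-16.7,-33.6,-19.4,102,102,
87,-34.6,-27.4,-29.7,-30.1,-39.4,-32.2,77,83,
88,-14.5,-35.5,-24.8,-18.4,-38.5,-26.4,97,98,
89,-40.0,-36.9,-23.6,-20.9,-41.6,-32.6,76,68,
90,-38.7,-22.0,-42.8,-36.4,-41.8,-36.3,54,51,
91,-35.8,-35.1,-39.0,-30.1,-39.7,-35.9,56,63,
92,-33.7,-32.3,-35.8,-33.5,-37.6,-34.6,66,82,
93,-33.3,-34.5,-36.9,-29.7,-34.9,-33.8,70,79,
94,-32.7,-36.3,-39.2,-29.7,-38.4,-35.3,61,69,
95,-33.4,-34.0,-19.5,-20.5,-41.7,-29.8,87,85,
96,-42.0,-37.0,-20.5,-15.5,-41.8,-31.3,81,66,
97,-32.5,-28.0,-31.1,-28.9,-16.7,-27.5,93,94,
98,-40.3,-35.2,-22.3,-23.0,-40.2,-32.2,78,77,
99,-36.0,-30.8,-37.0,-26.4,-39.4,-33.9,69,74,
100,-38.7,-37.5,-38.0,-22.6,-39.6,-35.3,60,64,
101,-22.1,-35.5,-36.3,-25.1,-16.7,-27.1,94,91,
102,-45.0,-16.7,4.0,-11.7,-40.8,-22.0,99,87,
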