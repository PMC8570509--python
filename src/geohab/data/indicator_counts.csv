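group,n_indicator_species,region
10,7,
12,8,
13,1,
15,6,
16,9,
18,1,
19,1,
20,1,
22,1,
23,1,
24,5,
28,1,
30,1,
31,1,
33,6,
34,1,
35,79,Jeju Province
40,2,
41,6,
46,2,
47,4,
49,1,
51,1,
54,1,
56,1,
57,24,Gangwon Province
58,12,Mt. Baekdu and Gaema Plateau
59,12,Mt. Baekdu and Gaema Plateau
501,5,
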