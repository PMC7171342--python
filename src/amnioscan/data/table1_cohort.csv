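sample_id,ls_ratio,lbc,gw,flm_outcome
1,1.84,1,18,control_18gw
2,1.50,2,18,control_18gw
3,1.57,2,18,control_18gw
4,1.94,2,18,control_18gw
5,1.30,2,18,control_18gw
6,2.27,1,18,control_18gw
7,1.71,2,18,control_18gw
8,5.05,75,32,premature
9,1.99,48,35,premature
10,2.13,56,36,premature
11,15.24,65,36,premature
12,33.92,57,39,mature
13,45.71,57,38,mature
14,99.69,58,37,mature
15,63.11,56,36,mature
16,96.00,53,35,mature
17,57.81,55,38,mature
18,41.36,55,37,mature
19,49.58,52,37,mature
20,61.14,57,39,mature
21,26.76,58,36,mature
22,54.35,48,39,mature
23,58.40,56,39,mature
24,55.85,56,37,mature
25,107.17,60,39,mature
26,65.10,60,37,mature
27,112.93,55,37,mature
28,18.88,53,37,mature
29,40.81,56,39,mature
30,46.72,53,37,mature
31,61.20,56,37,mature
32,33.92,53,38,mature
33,59.32,82,37,mature
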