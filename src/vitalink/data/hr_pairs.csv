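reading_no,measured,reference,error_pct
1,88,88,0.00
2,107,104,2.88
3,78,78,0.00
4,100,99,1.01
5,68,67,1.49
6,107,108,0.93
7,83,82,1.22
8,88,85,3.53
9,93,91,2.20
10,78,78,0.00
11,75,76,1.32
12,78,76,2.63
13,83,81,2.47
14,65,66,1.52
15,83,84,1.19
16,78,79,1.27
17,75,75,0.00
18,83,83,0.00
19,93,95,2.11
20,65,65,0.00
21,78,77,1.30
22,125,124,0.81
23,125,127,1.57
24,88,85,3.53
25,83,85,2.35
26,88,89,1.12
27,75,75,0.00
28,107,109,1.83
29,71,71,0.00
30,75,75,0.00
31,78,77,1.30
32,83,82,1.22
33,115,117,1.71
34,116,115,0.87
35,107,107,0.00
36,115,112,2.68
37,93,92,1.09
38,100,101,0.99
39,93,93,0.00
40,115,117,1.71
41,93,91,2.20
42,78,79,1.27
43,88,88,0.00
44,109,107,1.87
45,100,100,0.00
46,107,107,0.00
47,100,99,1.01
48,83,82,1.22
49,93,92,1.09
50,107,109,1.83
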