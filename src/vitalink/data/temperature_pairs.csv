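reading_no,measured,reference,error_pct
1,34.75,34.6,0.43
2,35.5,35.4,0.28
3,33,32.9,0.30
4,35.13,35.1,0.09
5,33.5,33.7,0.59
6,35.63,35.6,0.08
7,36.63,36.5,0.36
8,35.5,35.6,0.28
9,36.5,36.4,0.27
10,35.75,35.9,0.42
11,35.25,35.4,0.42
12,35.63,35.8,0.47
13,34.75,34.8,0.14
14,35.75,35.9,0.42
15,34.5,34.5,0.00
16,32.9,32.8,0.30
17,34.75,34.7,0.14
18,33.63,33.6,0.09
19,36,36.1,0.28
20,35.5,35.5,0.00
21,33.5,33.3,0.60
22,35.5,35.4,0.28
23,34.33,34.2,0.38
24,33.25,33.2,0.15
25,35.13,35,0.37
26,35.5,35.5,0.00
27,33.75,33.9,0.44
28,36.13,36.2,0.19
29,35.63,35.6,0.08
30,34.88,34.8,0.23
31,33.88,34.1,0.65
32,35.8,36.1,0.83
33,34.75,34.8,0.14
34,35.75,36,0.69
35,35.63,35.7,0.20
36,36.13,36.1,0.08
37,35.25,35,0.71
38,35.38,35.3,0.23
39,35.25,35.1,0.43
40,35.88,36.1,0.61
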