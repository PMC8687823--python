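reading_no,measured,reference,error_pct
1,99,98,1.02
2,98,97,1.03
3,100,98,2.04
4,99,99,0.00
5,100,99,1.01
6,97,98,1.02
7,98,99,1.01
8,99,98,1.02
9,98,98,0.00
10,99,99,0.00
11,99,99,0.00
12,99,99,0.00
13,99,100,1.00
14,100,98,2.04
15,99,100,1.00
16,99,97,2.06
17,100,99,1.01
18,99,98,1.02
19,100,99,1.01
20,99,98,1.02
21,98,97,1.03
22,100,100,0.00
23,99,99,0.00
24,100,98,2.04
25,98,99,1.01
26,99,97,2.06
27,99,100,1.00
28,98,98,0.00
29,97,99,2.02
30,98,99,1.01
31,99,98,1.02
32,98,98,0.00
33,99,97,2.06
34,100,99,1.01
35,99,98,1.02
36,98,97,1.03
37,98,100,2.00
38,98,99,1.01
39,98,98,0.00
40,99,98,1.02
41,97,98,1.02
42,100,100,0.00
43,100,99,1.01
44,97,99,2.02
45,97,97,0.00
46,98,99,1.01
47,100,99,1.01
48,99,99,0.00
49,98,97,1.03
50,99,100,1.00
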