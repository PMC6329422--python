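raw,scaled
<=12,62
13,74
14,80
15,84
16,87
17,89
18,91
19,93
20,94
21,96
22,97
23,98
24,100
25,101
26,102
27,103
28,104
29,105
30,106
31,107
32,108
33,109
34,110
35,111
36,112
37,113
38,114
39,115
40,116
41,117
42,118
43,119
44,120
45,121
46,123
47,124
48,125
49,126
50,128
51,129
52,131
53,133
54,135
55,137
56,139
57,143
58,147
59-60,154
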