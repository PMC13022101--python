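r,g,b
11,4,5
13,4,6
14,5,8
15,6,9
16,6,10
17,7,12
18,8,13
19,9,15
20,9,16
21,10,18
22,11,19
23,12,21
24,13,22
25,14,24
26,14,25
27,15,26
28,16,28
29,17,29
30,17,31
31,18,32
32,19,34
33,20,35
34,20,37
35,21,38
36,22,40
37,23,41
38,23,43
39,24,45
40,25,46
41,25,48
41,26,49
42,27,51
43,28,53
44,28,54
45,29,56
46,30,57
46,30,59
47,31,61
48,32,62
49,33,64
49,33,66
50,34,67
51,35,69
52,36,71
52,37,72
53,37,74
53,38,76
54,39,77
55,40,79
55,40,81
56,41,83
56,42,84
57,43,86
58,44,88
58,44,89
59,45,91
59,46,93
59,47,95
60,48,96
60,49,98
61,49,100
61,50,102
62,51,103
62,52,105
62,53,107
63,54,109
63,54,111
63,55,112
64,56,114
64,57,116
64,58,118
64,59,120
64,60,121
65,61,123
65,62,125
65,62,127
65,63,128
65,64,130
65,65,132
65,66,133
65,67,135
65,68,136
64,70,138
64,71,139
64,72,141
64,73,142
63,74,143
63,75,144
63,76,146
62,77,147
62,79,148
62,80,149
61,81,149
61,82,150
60,83,151
60,85,152
59,86,152
59,87,153
59,88,154
58,89,154
58,91,155
58,92,155
57,93,156
57,94,156
56,95,156
56,97,157
56,98,157
56,99,157
55,100,158
55,101,158
55,102,158
55,104,159
54,105,159
54,106,159
54,107,159
54,108,160
54,109,160
54,111,160
54,112,160
54,113,160
53,114,161
53,115,161
53,116,161
53,117,161
53,118,162
53,120,162
53,121,162
53,122,162
53,123,163
53,124,163
53,125,163
53,126,164
52,127,164
52,128,164
52,130,164
52,131,165
52,132,165
52,133,165
52,134,165
52,135,166
52,136,166
52,137,166
52,139,166
52,140,167
52,141,167
52,142,167
52,143,167
52,144,168
52,145,168
52,146,168
52,147,168
52,149,169
52,150,169
52,151,169
52,152,169
52,153,170
52,154,170
53,155,170
53,156,170
53,158,170
53,159,171
53,160,171
53,161,171
54,162,171
54,163,171
54,164,171
55,165,172
55,166,172
55,168,172
56,169,172
56,170,172
57,171,172
57,172,172
58,173,172
58,174,173
59,175,173
60,177,173
60,178,173
61,179,173
62,180,173
63,181,173
63,182,173
64,183,173
65,184,173
66,185,173
67,186,173
68,188,173
69,189,173
70,190,173
71,191,173
72,192,173
73,193,173
75,194,173
76,195,173
77,196,173
79,197,173
80,198,173
82,199,173
83,201,173
85,202,173
87,203,173
89,204,173
91,205,173
94,205,173
96,206,172
98,207,172
101,208,173
104,209,173
106,210,173
109,211,173
112,212,173
115,212,173
118,213,174
121,214,174
124,214,175
127,215,175
130,216,176
133,217,177
136,217,177
139,218,178
142,219,179
145,219,180
148,220,181
150,221,181
153,221,182
156,222,183
158,223,184
161,223,185
164,224,187
166,225,188
169,225,189
171,226,190
174,227,192
176,228,193
178,228,194
181,229,196
183,230,197
185,230,199
187,231,200
190,232,202
192,233,204
194,233,205
196,234,207
198,235,209
200,236,210
202,237,212
204,237,214
206,238,215
208,239,217
210,240,219
212,241,220
214,241,222
216,242,224
218,243,225
220,244,227
222,245,229
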