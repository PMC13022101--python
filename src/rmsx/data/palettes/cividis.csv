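r,g,b
0,34,78
0,35,79
0,36,81
0,37,83
0,37,84
0,38,86
0,39,88
0,40,89
0,40,91
0,41,93
0,42,95
0,42,97
0,43,98
0,44,100
0,44,102
0,45,104
0,46,106
0,46,108
0,47,109
0,48,111
0,48,112
0,49,112
0,49,113
1,50,113
5,51,113
8,51,112
12,52,112
15,53,112
18,53,112
20,54,112
22,55,112
24,55,111
26,56,111
28,57,111
30,58,111
32,58,111
33,59,110
35,60,110
36,60,110
38,61,110
39,62,110
41,63,110
42,63,109
43,64,109
45,65,109
46,65,109
47,66,109
49,67,109
50,67,109
51,68,109
52,69,108
53,69,108
54,70,108
56,71,108
57,72,108
58,72,108
59,73,108
60,74,108
61,74,108
62,75,108
63,76,108
64,76,108
65,77,108
66,78,108
67,78,108
68,79,108
69,80,108
70,81,108
71,81,108
72,82,108
73,83,108
74,83,108
75,84,108
76,85,108
77,85,108
78,86,108
79,87,108
80,87,108
81,88,109
82,89,109
83,90,109
84,90,109
85,91,109
85,92,109
86,92,109
87,93,109
88,94,109
89,94,110
90,95,110
91,96,110
92,97,110
93,97,110
94,98,110
94,99,111
95,99,111
96,100,111
97,101,111
98,101,111
99,102,112
100,103,112
101,104,112
101,104,112
102,105,112
103,106,113
104,106,113
105,107,113
106,108,113
107,109,114
108,109,114
108,110,114
109,111,114
110,111,115
111,112,115
112,113,115
113,114,116
114,114,116
114,115,116
115,116,117
116,116,117
117,117,117
118,118,118
119,119,118
119,119,119
120,120,119
121,121,119
122,122,120
123,122,120
124,123,120
125,124,120
126,124,120
126,125,120
127,126,120
128,127,120
129,127,120
130,128,121
131,129,121
132,130,121
133,130,121
134,131,121
135,132,120
136,133,120
137,133,120
138,134,120
139,135,120
140,136,120
141,136,120
142,137,120
143,138,120
144,139,120
145,139,120
146,140,120
146,141,120
147,142,120
148,142,119
149,143,119
150,144,119
151,145,119
152,146,119
153,146,119
154,147,118
155,148,118
156,149,118
157,149,118
158,150,118
159,151,117
160,152,117
161,153,117
162,153,117
163,154,116
164,155,116
165,156,116
166,156,116
167,157,115
168,158,115
169,159,115
170,160,115
171,160,114
172,161,114
173,162,114
174,163,113
175,164,113
176,165,113
177,165,112
179,166,112
180,167,111
181,168,111
182,169,111
183,169,110
184,170,110
185,171,109
186,172,109
187,173,109
188,174,108
189,174,108
190,175,107
191,176,107
192,177,106
193,178,106
194,179,105
195,179,105
196,180,104
197,181,104
198,182,103
199,183,103
200,184,102
201,185,101
203,185,101
204,186,100
205,187,99
206,188,99
207,189,98
208,190,98
209,191,97
210,192,96
211,192,95
212,193,95
213,194,94
214,195,93
215,196,92
217,197,92
218,198,91
219,199,90
220,200,89
221,200,88
222,201,88
223,202,87
224,203,86
225,204,85
226,205,84
228,206,83
229,207,82
230,208,81
231,209,80
232,210,79
233,211,78
234,211,76
235,212,75
237,213,74
238,214,73
239,215,72
240,216,70
241,217,69
242,218,68
243,219,66
245,220,65
246,221,63
247,222,62
248,223,60
249,224,58
251,225,56
252,226,54
253,227,52
254,228,52
254,229,53
254,230,54
254,232,56
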