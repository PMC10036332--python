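chymotrypsin_position	reference_index
1	0
2	1
3	2
4	3
5	4
6	5
7	6
8	7
9	8
10	9
11	10
12	11
13	12
16	13
17	14
18	15
19	16
20	17
21	18
22	19
23	20
24	21
25	22
26	23
27	24
28	25
29	26
30	27
31	28
32	29
33	30
34	31
35	32
36	33
37	34
38	35
39	36
40	37
41	38
42	39
43	40
44	41
45	42
46	43
47	44
48	45
49	46
50	47
51	48
52	49
53	50
54	51
55	52
56	53
57	54
58	55
59	56
60	57
61	58
62	59
63	60
64	61
65	62
66	63
67	64
68	65
69	66
70	67
71	68
72	69
73	70
74	71
75	72
76	73
77	74
78	75
79	76
80	77
81	78
82	79
83	80
84	81
85	82
86	83
87	84
88	85
89	86
90	87
91	88
92	89
93	90
94	91
95	92
96	93
97	94
98	95
99	96
100	97
101	98
102	99
103	100
104	101
105	102
106	103
107	104
108	105
109	106
110	107
111	108
112	109
113	110
114	111
115	112
116	113
117	114
118	115
119	116
120	117
121	118
122	119
123	120
124	121
125	122
126	123
127	124
128	125
129	126
130	127
131	128
132	129
133	130
134	131
135	132
136	133
137	134
138	135
139	136
140	137
141	138
142	139
143	140
144	141
145	142
146	143
149	144
150	145
151	146
152	147
153	148
154	149
155	150
156	151
157	152
158	153
159	154
160	155
161	156
162	157
163	158
164	159
165	160
166	161
167	162
168	163
169	164
170	165
171	166
172	167
173	168
174	169
175	170
176	171
177	172
178	173
179	174
180	175
181	176
182	177
183	178
184	179
185	180
186	181
187	182
188	183
189	184
190	185
191	186
192	187
193	188
194	189
195	190
196	191
197	192
198	193
199	194
200	195
201	196
202	197
203	198
204	199
205	200
206	201
207	202
208	203
209	204
210	205
211	206
212	207
213	208
214	209
215	210
216	211
217	212
218	213
219	214
220	215
221	216
222	217
223	218
224	219
225	220
226	221
227	222
228	223
229	224
230	225
231	226
232	227
233	228
234	229
235	230
236	231
237	232
238	233
239	234
240	235
241	236
242	237
243	238
244	239
245	240
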