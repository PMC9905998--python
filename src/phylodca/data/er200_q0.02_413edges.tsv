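# n_sites=200 edge_prob=0.02 seed=162
0	5
0	87
0	97
0	178
2	5
2	9
2	100
2	153
3	76
3	99
3	158
3	191
4	19
4	119
4	132
4	134
4	140
4	188
5	109
5	181
6	37
6	111
6	154
6	160
6	171
7	11
7	33
7	120
7	177
7	182
7	193
8	54
8	116
8	136
9	16
9	27
9	60
10	26
10	58
10	59
10	60
10	88
10	108
10	132
10	149
11	30
11	79
11	98
11	149
11	156
12	72
12	162
13	58
13	69
13	112
14	36
14	108
14	188
15	72
15	82
15	142
15	159
15	198
16	28
16	34
16	66
16	149
16	166
17	69
17	106
17	138
17	153
18	26
18	33
18	42
18	75
18	168
19	63
19	180
20	154
20	187
21	23
21	105
21	158
22	106
22	140
22	192
23	56
23	91
23	92
23	148
23	158
23	163
24	34
24	39
24	113
24	124
24	181
25	39
25	78
25	123
25	167
26	60
26	79
26	193
27	116
27	117
28	63
28	65
28	112
28	139
29	57
29	70
29	78
29	79
29	108
29	115
29	177
29	184
30	41
30	67
30	78
30	134
31	46
31	149
32	38
32	47
32	71
32	91
32	92
32	134
32	149
33	83
33	97
33	117
33	166
34	41
34	46
34	119
35	87
35	91
35	99
35	134
35	153
35	154
35	192
36	56
36	174
36	180
37	38
37	44
38	67
38	70
38	122
38	126
38	137
38	168
38	178
38	179
39	121
39	126
40	50
40	52
40	64
40	108
40	112
40	123
41	135
41	142
42	73
42	113
42	166
43	89
44	52
44	78
44	96
44	196
45	74
45	80
45	129
45	134
46	68
46	126
46	139
46	189
47	118
47	144
47	170
49	127
49	131
49	147
49	166
49	167
49	171
50	54
50	106
51	136
51	169
51	170
51	175
52	131
52	146
53	77
53	104
53	115
53	177
54	62
54	130
55	156
56	92
56	177
56	182
56	194
57	110
57	131
57	169
57	174
57	176
57	198
58	153
58	164
59	67
59	143
59	194
60	89
61	69
61	131
61	197
62	63
62	80
62	147
62	171
62	198
64	69
64	70
64	93
64	149
64	182
65	78
65	167
65	197
66	129
66	171
67	100
67	174
68	100
68	146
68	169
69	144
69	146
70	113
70	199
71	95
71	149
72	96
72	99
72	183
74	105
75	157
75	192
76	162
76	199
77	107
78	116
79	147
80	143
80	160
81	98
81	139
81	153
81	188
82	132
83	169
84	99
84	161
84	180
85	110
85	137
85	139
85	167
86	132
86	140
87	104
87	136
87	170
88	151
88	158
89	97
89	198
90	125
90	139
91	139
91	145
92	132
92	144
93	142
93	150
93	170
94	122
95	133
96	102
96	169
97	136
97	153
99	131
99	139
99	180
99	185
100	140
100	183
101	196
102	158
104	152
104	174
104	195
105	113
106	127
106	164
106	171
107	163
108	181
108	187
109	186
111	129
113	137
113	167
114	163
114	184
115	189
116	144
116	156
116	166
117	120
117	125
117	139
117	144
117	164
118	181
119	197
120	180
121	136
122	170
123	127
123	133
123	134
124	129
124	165
124	173
126	176
127	141
127	158
127	186
128	147
128	173
128	191
131	193
132	158
132	166
133	150
134	135
134	172
135	161
135	166
135	168
139	167
139	173
139	198
140	161
142	150
142	172
143	170
143	192
144	190
145	195
146	161
146	165
147	186
150	160
150	193
151	164
153	185
154	173
156	171
156	176
156	179
157	185
158	163
158	167
159	182
161	162
161	165
161	196
162	199
163	188
163	189
163	192
164	199
165	170
165	175
165	195
167	172
168	175
170	196
170	198
171	198
172	182
173	197
174	188
180	199
182	187
183	188
187	190
193	196
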