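index	label
1	PreCG.L
2	PreCG.R
3	SFGdor.L
4	SFGdor.R
5	Orbsup.L
6	Orbsup.R
7	MFG.L
8	MFG.R
9	Orbmid.L
10	Orbmid.R
11	IFGoperc.L
12	IFGoperc.R
13	IFGtriang.L
14	IFGtriang.R
15	Orbinf.L
16	Orbinf.R
17	ROL.L
18	ROL.R
19	SMA.L
20	SMA.R
21	OLF.L
22	OLF.R
23	SFGmed.L
24	SFGmed.R
25	Orbsupmid.L
26	Orbsupmid.R
27	REC.L
28	REC.R
29	INS.L
30	INS.R
31	ACG.L
32	ACG.R
33	DCG.L
34	DCG.R
35	PCG.L
36	PCG.R
37	HIP.L
38	HIP.R
39	PHG.L
40	PHG.R
41	AMYG.L
42	AMYG.R
43	CAL.L
44	CAL.R
45	CUN.L
46	CUN.R
47	Ling.L
48	Ling.R
49	SOG.L
50	SOG.R
51	MOG.L
52	MOG.R
53	IOG.L
54	IOG.R
55	FFG.L
56	FFG.R
57	PoCG.L
58	PoCG.R
59	SPG.L
60	SPG.R
61	IPL.L
62	IPL.R
63	SMG.L
64	SMG.R
65	ANG.L
66	ANG.R
67	PCUN.L
68	PCUN.R
69	PCL.L
70	PCL.R
71	CAU.L
72	CAU.R
73	PUT.L
74	PUT.R
75	PAL.L
76	PAL.R
77	THA.L
78	THA.R
79	HES.L
80	HES.R
81	STG.L
82	STG.R
83	TPOsup.L
84	TPOsup.R
85	MTG.L
86	MTG.R
87	TPOmid.L
88	TPOmid.R
89	ITG.L
90	ITG.R
91	Crus1.L
92	Crus1.R
93	Crus2.L
94	Crus2.R
95	C3.L
96	C3.R
97	C45.L
98	C45.R
99	C6.L
100	C6.R
101	C7b.L
102	C7b.R
103	C8.L
104	C8.R
105	C9.L
106	C9.R
107	C10.L
108	C10.R
109	V12
110	V3
111	V45
112	V6
113	V7
114	V8
115	V9
116	V10
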