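panel	stratum	cell_class	observed	expected	p_printed
all	autosomes	somatic	55	66.5	0.5964
all	autosomes	mitotic	184	170.5	0.8445
all	autosomes	meiotic	88	181.1	0.0001
all	autosomes	postmeiotic	211	120.0	0.0001
all	X	somatic	9	12.4	1
all	X	mitotic	26	37.5	0.0222
all	X	postmeiotic	34	19.1	0.0006
higher	autosomes	somatic	34	24.1	0.1519
higher	autosomes	mitotic	151	61.8	0.0001
higher	autosomes	meiotic	6	65.6	0.0001
higher	autosomes	postmeiotic	4	43.5	0.0001
higher	X	somatic	8	11.6	0.9903
higher	X	mitotic	25	35.3	0.0369
higher	X	postmeiotic	32	18.0	0.0008
lower	autosomes	somatic	11	31.4	0.0001
lower	autosomes	mitotic	9	80.5	0.0001
lower	autosomes	meiotic	54	85.5	0.0032
lower	autosomes	postmeiotic	180	56.6	0.0001
lower	X	somatic	0	0.2	1
lower	X	mitotic	0	0.5	1
lower	X	postmeiotic	1	0.3	0.8323
intermediate	autosomes	somatic	10	11	1
intermediate	autosomes	mitotic	24	28.2	1
intermediate	autosomes	meiotic	28	30	1
intermediate	autosomes	postmeiotic	27	19.8	0.2983
intermediate	X	somatic	1	0.5	1
intermediate	X	mitotic	1	1.6	1
intermediate	X	postmeiotic	1	0.8	1
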