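panel	stratum	cell_class	observed	expected	p_printed
all	autosomes	somatic	80	85.9	1
all	autosomes	mitotic	172	220.2	0.0003
all	autosomes	meiotic	284	233.9	0.0003
all	autosomes	postmeiotic	159	155.0	1
all	X	somatic	5	3.0	0.6300
all	X	mitotic	6	9.2	0.4345
all	X	postmeiotic	6	4.7	1
higher_domesticus	autosomes	somatic	31	38.8	0.7937
higher_domesticus	autosomes	mitotic	52	99.5	0.0001
higher_domesticus	autosomes	meiotic	154	105.7	0.0001
higher_domesticus	autosomes	postmeiotic	77	70.0	1
higher_domesticus	X	somatic	1	1.1	1
higher_domesticus	X	mitotic	2	3.3	1
higher_domesticus	X	postmeiotic	3	1.7	1
higher_musculus	autosomes	somatic	49	47.1	1
higher_musculus	autosomes	mitotic	120	120.7	1
higher_musculus	autosomes	meiotic	130	128.2	1
higher_musculus	autosomes	postmeiotic	82	85.0	1
higher_musculus	X	somatic	4	2.0	0.1182
higher_musculus	X	mitotic	4	6.0	0.2455
higher_musculus	X	postmeiotic	3	3.1	1
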