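Concept	Ontology	I	R	C	E	IC	FN	TN	Disregarded
CL	CLO	65	1	4	316	83	114	221	114
CL	CL	409	0	1	323	15	54	2	114
CL	UBERON	488	0	2	270	4	27	13	114
CL	BTO	55	0	7	244	76	122	300	114
CT	CL	282	26	4	333	9	16	3	23
CT	UBERON	415	0	0	237	4	14	3	23
CT	BTO	62	1	5	256	84	64	201	23
A	UBERON	84	4	0	109	0	1	0	10
A	BTO	17	0	1	115	19	18	28	10
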