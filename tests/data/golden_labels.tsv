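chrom	pos	ref	alt	build	gene	whole_brain	brain_cortex	brain_cerebellum	brain_basal_ganglia	spinal_cord	heart	kidney	liver	lung	skeletal_muscle	skin	testis	nerve_tibial	whole_blood
1	100	A	G	GRCh37	TNNT2	0	0	0	0	0	1	0	0	0	0	0	0	0	0
1	101	A	C	GRCh37	TNNT2	0	0	0	0	0	1	0	0	0	0	0	0	0	0
1	103	C	T	GRCh37	TNNT2	0	0	0	0	0	0	0	0	0	0	0	0	0	0
1	104	G	A	GRCh37	TNNT2	0	0	0	0	0	1	0	0	0	0	0	0	0	0
1	200	A	G	GRCh37	AHDC1	1	0	0	0	0	0	0	0	0	0	0	0	0	0
1	201	C	T	GRCh37	AHDC1	1	0	0	0	0	0	0	0	0	0	0	0	0	0
1	202	G	A	GRCh37	AHDC1	0	0	0	0	0	0	0	0	0	0	0	0	0	0
1	300	A	G	GRCh37	SGCG	0	0	0	0	0	0	0	0	0	1	0	0	0	0
1	301	C	T	GRCh37	SGCG	0	0	0	0	0	0	0	0	0	0	0	0	0	0
1	302	G	C	GRCh37	SGCG	0	0	0	0	0	0	0	0	0	0	0	0	0	0
1	400	A	G	GRCh37	PKD1	0	0	0	0	0	0	1	0	0	0	0	0	0	0
1	401	C	A	GRCh37	PKD1	0	0	0	0	0	1	1	0	0	0	0	0	0	0
1	501	C	T	GRCh37	LIVG	0	0	0	0	0	0	0	0	0	0	0	0	0	0
1	600	A	G	GRCh37	DUO	0	0	0	0	0	1	0	1	0	0	0	0	0	0
1	800	A	G	GRCh37	NEW1	0	0	0	0	0	0	0	0	0	0	0	0	0	0
1	900	A	G	GRCh37	NEW2	1	0	0	0	0	0	0	0	0	0	0	0	0	0
1	1000	A	G	GRCh37	BG1	0	0	0	0	0	0	0	0	0	0	0	0	0	0
1	1001	C	T	GRCh37	BG1	0	0	0	0	0	0	0	0	0	0	0	0	0	0
1	1002	G	A	GRCh37	BG1	0	0	0	0	0	0	0	0	0	0	0	0	0	0
1	1101	C	T	GRCh37	BG2	0	0	0	0	0	0	0	0	0	0	0	0	0	0
1	1200	A	G	GRCh37	BG3	0	0	0	0	0	0	0	0	0	0	0	0	0	0
1	105	T	C	GRCh37	TNNT2	0	0	0	0	0	1	0	0	0	0	0	0	0	0
1	1300	A	G	GRCh37	MYO7A	1	0	0	0	0	0	0	0	0	0	0	0	0	0
1	1301	C	T	GRCh37	MYO7A	0	0	0	0	0	0	0	0	0	0	0	0	0	0
1	1302	G	T	GRCh37	MYO7A	0	0	0	0	0	0	0	0	0	0	0	0	0	0
1	1400	A	G	GRCh37	BG4	0	0	0	0	0	0	0	0	0	0	0	0	0	0
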