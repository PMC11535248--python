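chrom	pos	ref	alt	build	gene	score_a	score_b	consequence__missense	consequence__synonymous	consequence__stop_gained	expr__heart	expr__whole_brain
1	100	A	G	GRCh37	TNNT2	0.1	0.5	1	0	0	2.5	0.3
1	101	A	C	GRCh37	TNNT2	0.101	0.0505	0	0	1	2.5	0.3
1	103	C	T	GRCh37	TNNT2	0.1	0.0515	0	1	0	2.5	0.3
1	104	G	A	GRCh37	TNNT2	0.104	0.052	1	0	0	2.5	0.3
1	200	A	G	GRCh37	AHDC1	0.2	0.1	1	0	0	0.2	2.2
1	201	C	T	GRCh37	AHDC1	0.201	0.1005	0	0	1	0.2	2.2
1	202	G	A	GRCh37	AHDC1	0.202	0.101	0	1	0	0.2	2.2
1	300	A	G	GRCh37	SGCG	0.3	0.15	0	0	0	0.4	0.1
1	301	C	T	GRCh37	SGCG	0.301	0.1505	0	1	0	0.4	0.1
1	302	G	C	GRCh37	SGCG	0.302	0.151	0	0	0	0.4	0.1
1	400	A	G	GRCh37	PKD1	0.4	0.2	1	0	0	0.6	0.2
1	401	C	A	GRCh37	PKD1	0.401	0.2005	1	0	0	0.6	0.2
1	501	C	T	GRCh37	LIVG	0.501	0.2505	0	1	0	0.1	0.5
1	600	A	G	GRCh37	DUO	0.6	0.3	0	0	1	1.5	0.4
1	800	A	G	GRCh37	NEW1	0.8	0.4	0	1	0	0.7	0
1	900	A	G	GRCh37	NEW2	0.9	0.45	1	0	0	0	0
1	1000	A	G	GRCh37	BG1	1	0.5	0	1	0	0.25	0.35
1	1001	C	T	GRCh37	BG1	1.001	0.5005	0	1	0	0.25	0.35
1	1002	G	A	GRCh37	BG1	1.002	0.501	0	1	0	0.25	0.35
1	1101	C	T	GRCh37	BG2	1.101	0.5505	0	1	0	0.15	0.45
1	1200	A	G	GRCh37	BG3	1.2	0.6	0	1	0	0.05	0.55
1	105	T	C	GRCh37	TNNT2	0.105	0.0525	1	0	0	2.5	0.3
1	1300	A	G	GRCh37	MYO7A	1.3	0.65	1	0	0	0.3	1.8
1	1301	C	T	GRCh37	MYO7A	1.301	0.6505	0	1	0	0.3	1.8
1	1302	G	T	GRCh37	MYO7A	1.302	0.651	0	1	0	0.3	1.8
1	1400	A	G	GRCh37	BG4	1.4	0.7	0	1	0	0.2	0.6
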