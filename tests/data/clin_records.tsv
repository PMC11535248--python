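chrom	pos	ref	alt	gene	build	stars	clin_sig_simple	phenotype_omim_ids	annotation_year
1	100	A	G	TNNT2	GRCh37	2	1	601494	2020
1	101	A	C	TNNT2	GRCh37	3	1	601494	2021
1	102	A	T	TNNT2	GRCh37	1	1	601494	2020
1	103	C	T	TNNT2	GRCh37	2	0		2019
1	104	G	A	TNNT2	GRCh37	2	1	601494	2023
1	200	A	G	AHDC1	GRCh37	2	1	615829	2018
1	201	C	T	AHDC1	GRCh37	2	1	615829	2023
1	202	G	A	AHDC1	GRCh37	2	0		2024
1	300	A	G	SGCG	GRCh37	2	1	253700	2021
1	301	C	T	SGCG	GRCh37	2	0		2020
1	302	G	C	SGCG	GRCh37	2	0		2023
1	400	A	G	PKD1	GRCh37	2	1	208540	2016
1	401	C	A	PKD1	GRCh37	3	1	208540;601494	2020
1	500	A	G	LIVG	GRCh37	2	1	222222	2020
1	501	C	T	LIVG	GRCh37	2	0		2021
1	600	A	G	DUO	GRCh37	2	1	333333	2019
1	700	A	G	UNK	GRCh37	2	1	999999	2020
1	800	A	G	NEW1	GRCh37	2	0		2023
1	900	A	G	NEW2	GRCh37	2	1	615829	2024
1	1000	A	G	BG1	GRCh37	2	0		2017
1	1001	C	T	BG1	GRCh37	2	0		2022
1	1002	G	A	BG1	GRCh37	2	0		2023
1	1100	A	G	BG2	GRCh37	0	0		2020
1	1101	C	T	BG2	GRCh37	2	0		2020
1	1200	A	G	BG3	GRCh37	4	0		2018
1	105	T	C	TNNT2	GRCh37	2	1	601494	2022
1	1300	A	G	MYO7A	GRCh37	2	1	615829	2021
1	1301	C	T	MYO7A	GRCh37	2	0		2020
1	1302	G	T	MYO7A	GRCh37	2	0		2023
1	1400	A	G	BG4	GRCh37	3	0		2024
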