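variant_id	score_a	score_b	consequence
1:100:A:G:GRCh37	0.1		missense
1:101:A:C:GRCh37	0.101	0.0505	stop_gained
1:102:A:T:GRCh37	0.102	0.051	missense
1:103:C:T:GRCh37		0.0515	synonymous
1:104:G:A:GRCh37	0.104	0.052	missense
1:200:A:G:GRCh37	0.2	0.1	missense
1:201:C:T:GRCh37	0.201	0.1005	stop_gained
1:202:G:A:GRCh37	0.202	0.101	synonymous
1:300:A:G:GRCh37	0.3	0.15
1:301:C:T:GRCh37	0.301	0.1505	synonymous
1:302:G:C:GRCh37	0.302	0.151	intergenic
1:400:A:G:GRCh37	0.4	0.2	missense
1:401:C:A:GRCh37	0.401	0.2005	missense
1:500:A:G:GRCh37	0.5	0.25	missense
1:501:C:T:GRCh37	0.501	0.2505	synonymous
1:600:A:G:GRCh37	0.6	0.3	stop_gained
1:700:A:G:GRCh37	0.7	0.35	missense
1:800:A:G:GRCh37	0.8	0.4	synonymous
1:900:A:G:GRCh37	0.9	0.45	missense
1:1000:A:G:GRCh37	1.0	0.5	synonymous
1:1001:C:T:GRCh37	1.001	0.5005	synonymous
1:1002:G:A:GRCh37	1.002	0.501	synonymous
1:1100:A:G:GRCh37	1.1	0.55	synonymous
1:1101:C:T:GRCh37	1.101	0.5505	synonymous
1:1200:A:G:GRCh37	1.2	0.6	synonymous
1:105:T:C:GRCh37	0.105	0.0525	missense
1:1300:A:G:GRCh37	1.3	0.65	missense
1:1301:C:T:GRCh37	1.301	0.6505	synonymous
1:1302:G:T:GRCh37	1.302	0.651	synonymous
1:1400:A:G:GRCh37	1.4	0.7	synonymous
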