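gene	expr__heart	expr__whole_brain
TNNT2	2.5	0.3
AHDC1	0.2	2.2
SGCG	0.4	0.1
PKD1	0.6	0.2
LIVG	0.1	0.5
DUO	1.5	0.4
UNK	0.0	0.0
NEW1	0.7
BG1	0.25	0.35
BG2	0.15	0.45
BG3	0.05	0.55
MYO7A	0.3	1.8
BG4	0.2	0.6
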