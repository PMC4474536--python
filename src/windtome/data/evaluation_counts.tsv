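label	threshold	n_candidates	n_hits_primary	n_hits_class	pct_primary	pct_class
WinDTome	score_s>=3	264	39	74	14.8	28.0
WinDTome	score_s>=2	1354	76	102	5.6	7.5
WinDTome	score_s>=1	37680	191	292	0.5	0.8
DrugBank		490	45	87	9.2	17.8
KEGG		375	30	70	8.0	18.7
TTD		2388	27	62	1.1	2.6
MATADOR		374	48	82	12.8	21.9
PDSP		2001	39	59	1.9	2.9
BindingDB		34748	41	98	0.1	0.3
STITCH	combined>=0.7	32282	100	241	0.3	0.7
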