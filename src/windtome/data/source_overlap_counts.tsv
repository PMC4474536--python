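entity_kind	source_a	source_b	count_a	count_b	intersection	proportion
drug	DrugBank	KEGG	4316	1121	761	0.679
drug	DrugBank	TTD	4316	14073	1594	0.369
drug	DrugBank	MATADOR	4316	758	447	0.590
drug	DrugBank	PDSP	4316	4947	195	0.045
drug	DrugBank	BindingDB	4316	290874	1162	0.269
drug	KEGG	TTD	1121	14073	524	0.467
drug	KEGG	MATADOR	1121	758	417	0.550
drug	KEGG	PDSP	1121	4947	151	0.135
drug	KEGG	BindingDB	1121	290874	259	0.231
drug	TTD	MATADOR	14073	758	307	0.405
drug	TTD	PDSP	14073	4947	340	0.069
drug	TTD	BindingDB	14073	290874	5984	0.425
drug	MATADOR	PDSP	758	4947	151	0.199
drug	MATADOR	BindingDB	758	290874	129	0.170
drug	PDSP	BindingDB	4947	290874	22	0.004
target	DrugBank	KEGG	2102	474	295	0.622
target	DrugBank	TTD	2102	940	479	0.510
target	DrugBank	MATADOR	2102	1840	198	0.108
target	DrugBank	PDSP	2102	145	47	0.324
target	DrugBank	BindingDB	2102	2048	372	0.182
target	KEGG	TTD	474	940	198	0.418
target	KEGG	MATADOR	474	1840	194	0.409
target	KEGG	PDSP	474	145	41	0.283
target	KEGG	BindingDB	474	2048	165	0.348
target	TTD	MATADOR	940	1840	106	0.113
target	TTD	PDSP	940	145	63	0.434
target	TTD	BindingDB	940	2048	494	0.526
target	MATADOR	PDSP	1840	145	38	0.262
target	MATADOR	BindingDB	1840	2048	73	0.040
target	PDSP	BindingDB	145	2048	22	0.152
pair	DrugBank	KEGG	9886	3532	1553	0.440
pair	DrugBank	TTD	9886	22791	1976	0.200
pair	DrugBank	MATADOR	9886	10687	906	0.092
pair	DrugBank	PDSP	9886	11762	384	0.039
pair	DrugBank	BindingDB	9886	503378	1471	0.149
pair	KEGG	TTD	3532	22791	586	0.166
pair	KEGG	MATADOR	3532	10687	898	0.254
pair	KEGG	PDSP	3532	11762	237	0.067
pair	KEGG	BindingDB	3532	503378	415	0.117
pair	TTD	MATADOR	22791	10687	341	0.032
pair	TTD	PDSP	22791	11762	490	0.042
pair	TTD	BindingDB	22791	503378	8804	0.386
pair	MATADOR	PDSP	10687	11762	247	0.023
pair	MATADOR	BindingDB	10687	503378	179	0.017
pair	PDSP	BindingDB	11762	503378	81	0.007
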