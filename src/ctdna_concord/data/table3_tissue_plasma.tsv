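# APC / KRAS / TP53 mutation calls in matched tumor-tissue and plasma
# samples for the 16-patient cohort; one row per detected call.
# vaf_percent is the reported mutant-allele fraction in percent.
patient_id	sample_type	gene	hgvs_c	vaf_percent
14	tissue	APC	c.3736_3740del	33.3
14	tissue	TP53	c.637C>T	96.6
14	plasma	TP53	c.637C>T	0.7
29	tissue	APC	c.834G>A	35.9
29	tissue	APC	c.1312+2T>C	42.4
29	plasma	APC	c.834G>A	3.5
29	plasma	APC	c.1312+2T>C	6.3
32	tissue	APC	c.4432_4460del	81.7
32	tissue	APC	c.6614C>G	41.1
32	plasma	APC	c.4432_4460del	1.2
32	tissue	KRAS	c.35G>T	38.5
38	tissue	APC	c.4666dup	83.3
38	tissue	KRAS	c.183A>C	45.6
52	tissue	APC	c.1690C>T	16.3
52	tissue	APC	c.4476del	12.6
52	tissue	KRAS	c.38G>A	24.7
52	plasma	KRAS	c.38G>A	0.4
52	plasma	KRAS	c.404G>C	20
53	tissue	APC	c.646C>T	66.9
53	tissue	TP53	c.1010G>T	64.4
53	plasma	TP53	c.1010G>T	1.1
55	tissue	APC	c.2821G>T	19.4
55	tissue	APC	c.4364del	41.9
55	plasma	APC	c.4364del	4.7
55	tissue	KRAS	c.34G>A	61.9
55	plasma	KRAS	c.34G>A	9.8
59	plasma	APC	c.5463G>T	0.6
59	tissue	KRAS	c.38G>A	11.9
59	plasma	KRAS	c.38G>A	10.9
59	plasma	TP53	c.740A>G	0.5
68	tissue	TP53	c.817C>T	14.1
68	plasma	TP53	c.817C>T	5.9
73	tissue	APC	c.2932C>T	77.7
73	tissue	KRAS	c.35G>A	53.9
73	tissue	TP53	c.586C>T	79.1
75	tissue	APC	c.1213C>T	52.7
75	tissue	APC	c.1409-1G>A	28.7
75	tissue	APC	c.4348C>T	55.6
75	plasma	APC	c.1213C>T	9.7
75	plasma	APC	c.1409-1G>A	11.3
75	plasma	APC	c.4348C>T	9.0
75	tissue	KRAS	c.35G>T	57.7
75	plasma	KRAS	c.35G>T	17.2
78	tissue	APC	c.3340C>T	42.1
78	tissue	APC	c.4215dup	43.1
78	plasma	APC	c.3340C>T	19.5
78	plasma	APC	c.4215dup	20.7
78	plasma	APC	c.6747del	0.4
78	tissue	KRAS	c.35G>A	57.8
78	plasma	KRAS	c.35G>A	45.9
78	tissue	TP53	c.632C>T	45.7
78	tissue	TP53	c.454C>T	44.4
78	plasma	TP53	c.632C>T	22.9
78	plasma	TP53	c.454C>T	19.4
83	tissue	TP53	c.524G>A	35.0
83	plasma	TP53	c.524G>A	1.7
84	tissue	APC	c.1387dup	78.3
84	plasma	APC	c.1387dup	0.8
84	tissue	KRAS	c.35G>T	61.8
84	plasma	KRAS	c.35G>T	0.6
84	tissue	TP53	c.1024C>T	77.6
84	plasma	TP53	c.1024C>T	1.5
85	tissue	APC	c.4064_4065insA	81.5
85	plasma	APC	c.4064_4065insA	14.3
85	tissue	KRAS	c.437C>T	79.2
85	plasma	KRAS	c.437C>T	6.2
85	tissue	TP53	c.480_482del	80.1
85	plasma	TP53	c.480_482del	8.0
85	plasma	TP53	c.761T>G	0.2
85	plasma	TP53	c.743G>A	3.5
85	plasma	TP53	c.451C>A	0.2
85	plasma	TP53	c.379T>C	0.2
96	tissue	APC	c.1548+1G>T	29.7
96	tissue	APC	c.4127_4128del	62.9
96	plasma	APC	c.1548+1G>T	10
96	plasma	APC	c.4127_4128del	29.3
96	tissue	KRAS	c.34G>A	44.6
96	plasma	KRAS	c.34G>A	17
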