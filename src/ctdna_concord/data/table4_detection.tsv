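# Per-patient somatic mutation counts: mutations called in tumor tissue and
# the subset of those also detected in the matched plasma sample.
patient_id	tissue_mutations	detected_in_plasma
14	13	8
29	19	12
32	16	5
38	14	7
52	23	5
53	15	10
55	15	11
59	99	87
68	11	7
73	24	14
75	11	11
78	19	17
83	22	18
84	16	11
85	18	17
96	22	22
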