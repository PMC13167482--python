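# Actionable-gene (BRAF / PIK3CA / EGFR) mutation calls in matched tissue
# and plasma for the 16-patient cohort; one row per patient.
# Cells are semicolon-joined GENE|hgvs_c|vaf_percent entries, "." = none.
patient_id	tissue	plasma
14	BRAF|c.95_100del|23.4	.
29	BRAF|c.95_100del|15.8	.
32	PIK3CA|c.1633G>A|40.3	.
38	.	.
52	PIK3CA|c.1633G>A|13.2	.
53	BRAF|c.94G>C|25	BRAF|c.94G>C|11.8
55	.	.
59	.	EGFR|c.1159_1160del|0.3
68	.	.
73	.	.
75	PIK3CA|c.3140A>G|50.0	PIK3CA|c.3140A>G|12.0
78	.	BRAF|c.2257del|0.3
83	.	.
84	.	PIK3CA|c.1624G>A|0.6
85	.	.
96	.	BRAF|c.209G>A|9.6;EGFR|c.412A>G|0.5
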