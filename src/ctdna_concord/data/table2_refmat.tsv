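# Reference-material VAF panel: 38 variants with theoretical allele
# frequencies (%) and observed VAF (%) per extraction arm.
# solid_phase_af = direct solid-phase extraction arm;
# liquid_liquid_af = liquid-liquid extraction arm; NA = not detected.
gene	cosmic_id	theoretical_af	solid_phase_af	liquid_liquid_af
AKT1	COSM33765	0.525	NA	0.24
APC	COSM13127	0.510	0.66	0.30
APC	COSM18561	0.435	0.83	0.53
ATM	COSM21924	0.630	0.63	0.59
BRAF	COSM476	0.525	NA	0.89
CTNNB1	COSM5664	0.665	0.30	0.28
EGFR	COSM6224	0.615	0.79	0.54
EGFR	COSM12378	0.565	0.21	0.69
EGFR	COSM6225	0.580	0.64	0.46
EGFR	COSM6240	0.565	0.45	0.72
ERBB2	COSM20959	0.490	NA	NA
FGFR3	COSM715	0.550	NA	0.46
FLT3	COSM783	0.490	0.64	0.40
FOXL2	COSM33661	0.480	0.63	0.44
GNA11	COSM52969	0.690	0.79	0.65
GNAQ	COSM28758	0.490	0.38	0.15
GNAS	COSM27887	0.585	0.90	0.69
IDH1	COSM28747	0.665	NA	0.25
JAK2	COSM12600	0.500	NA	0.31
KIT	COSM1314	0.555	0.42	0.49
KRAS	COSM521	0.490	0.38	0.31
MPL	COSM18918	0.545	0.26	0.31
NPM1	COSM17559	0.395	NA	NA
NRAS	COSM584	0.625	0.40	0.79
PDGFRA	COSM736	0.565	0.33	0.45
PDGFRA	COSM28053	0.570	0.30	0.38
PIK3CA	COSM763	0.425	1.60	0.89
PIK3CA	COSM12464	0.460	1.05	0.60
PIK3CA	COSM775	0.555	0.33	0.98
PTEN	COSM4986	0.540	0.40	1.06
PTEN	COSM5809	0.540	1.20	1.21
RET	COSM965	0.535	1.22	0.27
SMAD4	COSM14105	0.500	0.70	1.07
TP53	COSM10648	0.570	0.61	0.44
TP53	COSM10660	0.525	1.23	0.55
TP53	COSM10662	0.530	0.20	0.50
TP53	COSM6530	0.470	0.21	0.34
TP53	COSM18610	not_tested	0.62	0.45
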