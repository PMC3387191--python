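# Default 9-SNP type-2-diabetes risk panel.
# or_literature: per-allele odds ratio for incident T2D. These are
# literature-typical European-ancestry values shipped as EDITABLE DEFAULTS,
# not authoritative estimates; replace with your own meta-analytic values
# for any real analysis. risk_allele_freq is likewise a plausible default
# used only by the synthetic-cohort generator.
rsid	gene	risk_allele	or_literature	secretion_related	risk_allele_freq
rs7903146	TCF7L2	T	1.37	true	0.30
rs7923837	HHEX	G	1.13	true	0.61
rs13266634	SLC30A8	C	1.12	true	0.70
rs1001013	WFS1	A	1.11	true	0.60
rs5219	KCNJ11	T	1.14	true	0.37
rs151290	KCNQ1	C	1.08	true	0.15
rs10830963	MTNR1B	G	1.09	true	0.28
rs8050136	FTO	A	1.17	false	0.40
rs1808282	PPARG	C	1.14	false	0.82
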