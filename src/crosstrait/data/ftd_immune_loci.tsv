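snp	chrom	nearest_gene	immune_trait	immune_p	min_conj_fdr	ftd_p	direction	in_hla_region
rs2269423	6	AGPAT1	CeD	4.63e-2	4.63e-2	6.28e-1	+/-	true
rs3117097	6	BTNL2	RA	8.21e-5	8.21e-5	7.19e-3	+/+	true
rs204989	6	GPSM3	UC	2.90e-2	9.02e-3	2.58e-1	+/+	true
rs204991	6	GPSM3	T1D	1.00e-2	9.02e-3	2.58e-1	+/+	true
rs17427887	6	HLA-DQA2	RA	3.70e-2	3.70e-2	6.02e-1	-/-	true
rs10484561	6	HLA-DQB1	T1D	1.86e-2	1.71e-2	4.17e-1	-/+	true
rs3135353	6	HLA-DRA	CD	2.29e-2	3.58e-3	1.35e-1	+/+	true
rs9268852	6	HLA-DRA	UC	1.25e-7	1.25e-7	1.03e-4	+/+	true
rs3129890	6	HLA-DRA	T1D	5.54e-5	5.54e-5	7.19e-3	+/+	true
rs6457590	6	HLA-DRA	RA	1.52e-2	1.52e-2	3.80e-1	+/+	true
rs9268877	6	HLA-DRA	RA	3.64e-7	1.25e-7	1.03e-4	+/-	true
rs875142	6	PAQR8	CD	4.62e-2	4.62e-2	5.51e-1	-/-	false
rs9261536	6	TRIM15	T1D	4.31e-2	4.31e-2	6.98e-1	-/+	true
rs3094138	6	TRIM26	T1D	4.63e-2	2.87e-2	6.28e-1	-/+	true
rs7778450	7	TNS3	CeD	4.26e-2	4.26e-2	6.17e-1	-/-	false
rs2192493	7	TWISTNB	T1D	4.17e-2	4.17e-2	6.09e-1	+/+	false
rs10216900	8	CR590356	T1D	3.09e-2	3.09e-2	6.40e-1	+/+	false
rs10784359	12	SLC2A13	RA	3.33e-2	3.33e-2	5.90e-1	+/+	false
rs17572851	17	MAPT	T1D	2.47e-2	2.47e-2	5.90e-1	+/+	false
rs199533	17	NSF	CD	3.90e-2	1.95e-2	4.56e-1	+/+	false
rs2134297	18	DCC	CeD	3.11e-2	3.11e-2	5.73e-1	+/+	false
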