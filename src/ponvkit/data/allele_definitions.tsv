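# Default star-allele definition table (editable; one row per defining
# variant, rows with variant_id '.' declare a default allele with no
# requirements).  Matching priority is the order of first appearance of each
# star allele within its gene.  Scores are per-allele activity values summed
# over the diplotype; for CYP2C9 the score is 1 for reduced-function alleles
# (counted, not summed as activity); CYP3A4/3A5/3A7 scores encode
# functional (1) vs non/low-functional (0) status used by the CYP3A
# group rule, not additive activities.
gene	star_allele	variant_id	required_allele	score
CYP1A2	*1A	.	.	1
CYP1A2	*1L	rs762551	A	1
CYP1A2	*1L	rs2069514	A	1
CYP1A2	*1F	rs762551	A	2
CYP1A2	*1C	rs2069514	A	0
CYP2B6	*1	.	.	1
CYP2B6	*6	rs3745274	T	0
CYP2B6	*6	rs2279343	G	0
CYP2B6	*9	rs3745274	T	1
CYP2B6	*4	rs2279343	G	2
CYP2B6	*22	rs34223104	C	2
CYP2B6	*5	rs3211371	T	0
CYP2C19	*1	.	.	1
CYP2C19	*2	rs4244285	A	0
CYP2C19	*3	rs4986893	A	0
CYP2C19	*17	rs12248560	T	2
CYP2C9	*1	.	.	0
CYP2C9	*2	rs1799853	T	1
CYP2C9	*3	rs1057910	C	1
CYP2D6	*1	.	.	1
CYP2D6	*4	rs3892097	A	0
CYP2D6	*3	rs35742686	-	0
CYP2D6	*6	rs5030655	-	0
CYP2D6	*10	rs1065852	T	0.5
CYP2D6	*41	rs28371725	T	0.5
CYP2D6	*9	rs5030656	-	0.5
CYP3A4	*1	.	.	1
CYP3A4	*22	rs35599367	T	0
CYP3A5	*1	.	.	1
CYP3A5	*3	rs776746	C	0
CYP3A7	*1	.	.	0
CYP3A7	*1C	rs45446698	G	1
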