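# Recessive variants in novel candidate genes/regions, transcribed from the
# published cohort table (A: homozygous SNVs with pRec scores; B: homozygous
# CNV deletions).  recurrence = additional carriers reported from external
# ASD cohorts.
family_id	sex	gene	variant_class	inheritance	impact	tier	prec	consanguineous	recurrence
BRK-83	male	EIF2A	snv_indel	homozygous_recessive	Dmiss	novel_candidate	0.96462	yes	0
BRK-83	male	TRIM29	snv_indel	homozygous_recessive	Dmiss	novel_candidate	0.91016	yes	0
BRK-23	male	CDH23	snv_indel	homozygous_recessive	LoF	novel_candidate	1	no	1
BRK-61	female	KDM8	snv_indel	homozygous_recessive	Dmiss	novel_candidate	0.98296	yes	0
BRK-61	female	NOC3L	snv_indel	homozygous_recessive	Dmiss	novel_candidate	0.95724	yes	0
BRK-71	male	IFT140	snv_indel	homozygous_recessive	Dmiss	novel_candidate	0.90704	yes	1
BRK-16	male	AFG3L1P	cnv	homozygous_recessive	deletion	novel_candidate		no	1
BRK-72	male	ELOVL2	cnv	homozygous_recessive	deletion	novel_candidate	0.15415	no	1
BRK-83	male	FAM204A	cnv	homozygous_recessive	deletion	novel_candidate	0.97978	yes	3
BRK-12	male	LINC00648/MIR548Y	cnv	homozygous_recessive	deletion	novel_candidate		no	0
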