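# Candidate variants in known ASD/NDD genes/regions, transcribed from the
# published cohort table (sections: dominant SNVs/indels, recessive
# SNVs/indels, X-linked SNVs/indels, CNVs, TREs, mtDNA).
# Notes:
# - the GRIN2B ACMG cell is printed "LPs"; treated as likely-pathogenic.
# - the two recessive variants of family BRK-74 (CTSA, ZNF335) lie on one
#   homozygous haplotype and count as a single event.
# - consanguinity is stated in aggregate for the recessive families (6 of 7
#   consanguineous; BRK-74 explicitly consanguineous in the text); BRK-87 is
#   arbitrarily taken as the single non-consanguineous recessive family.
family_id	sex	gene	variant_class	inheritance	impact	acmg	consanguineous
BRK-48	male	WDR37	snv_indel	de_novo	Dmiss	LP
BRK-52	female	STAG1	snv_indel	de_novo	Dmiss	P
BRK-98	female	SCN2A	snv_indel	de_novo	Dmiss	P
BRK-78	male	KDM5B	snv_indel	de_novo	Dmiss	LP
BRK-11	female	KCNMA1	snv_indel	de_novo	LoF	LP
BRK-86	male	EIF5A	snv_indel	de_novo	Dmiss	LP
BRK-73	male	MTOR	snv_indel	de_novo	Dmiss	LP
BRK-77	male	GRIN2B	snv_indel	de_novo	Dmiss	LPs
BRK-05	male	MYO5A	snv_indel	de_novo	Dmiss	LP
BRK-13	male	DNM1	snv_indel	inherited_dominant	Dmiss	VUS
BRK-87	male	NBN	snv_indel	homozygous_recessive	Dmiss	VUS	no
BRK-88	female	TRAPPC9	snv_indel	homozygous_recessive	LoF	P/LP	yes
BRK-54	female	TSEN2	snv_indel	homozygous_recessive	Dmiss	VUS	yes
BRK-57	female	UBR1	snv_indel	homozygous_recessive	Dmiss	VUS	yes
BRK-58	male	MED17	snv_indel	homozygous_recessive	Dmiss	VUS	yes
BRK-59	male	TIAM1	snv_indel	homozygous_recessive	Dmiss	VUS	yes
BRK-74	male	CTSA	snv_indel	homozygous_recessive	Dmiss	VUS	yes
BRK-74	male	ZNF335	snv_indel	homozygous_recessive	Dmiss	VUS	yes
BRK-41	male	PTCHD1	snv_indel	x_linked_recessive	Dmiss	VUS
BRK-43	male	DMD	snv_indel	x_linked_recessive	Dmiss	VUS
BRK-56	male	SLC9A6	snv_indel	x_linked_recessive	Dmiss	VUS
BRK-76	male	WNK3	snv_indel	x_linked_recessive	Dmiss	VUS
BRK-96	male	WNK3	snv_indel	x_linked_recessive	Dmiss	VUS
BRK-81	male	22q11.21	cnv	de_novo	deletion	P
BRK-65	male	16p13.3	cnv	inherited_dominant	duplication	VUS
BRK-51	female	SHANK2	tre	dominant	tre
BRK-89	female	NCOR2	tre	dominant	tre
BRK-16	male	MT-TL1	mtdna	de_novo	mt_variant
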