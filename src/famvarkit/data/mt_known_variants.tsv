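# Known pathogenic mtDNA variants screened at > 2% heteroplasmy.  Only the
# three variants named in the cohort report are listed; the full published
# lists (15 ASD-associated, 6 homoplasmic-disorder) can be supplied as a
# user TSV of the same shape.
position	ref	alt	disorder	list_type
3243	A	G	MELAS	asd_associated
11778	G	A	LHON	homoplasmic_disorder
14484	T	C	LHON	homoplasmic_disorder
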