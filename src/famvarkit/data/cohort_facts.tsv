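# Cohort-level facts stated in the study text: 100 families, 44
# consanguineous, 104 probands (88 male / 16 female).
n_families	n_consanguineous	probands_male	probands_female
100	44	88	16
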