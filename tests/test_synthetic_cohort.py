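"""Generator properties: determinism, pedigree structure, Mendelian
consistency, and plant placement."""

import numpy as np
import pytest

from famvarkit.io_formats import Family, Member, Pedigree, read_ped
from famvarkit.relatedness import genotype_matrix
from famvarkit.synthetic_cohort import (CohortSpec, PlantError,
                                        simulate_cohort, simulate_genotypes,
                                        simulate_pedigrees)

SMALL_PLAN = {"de_novo_snv": 2, "homozygous_recessive": 2, "x_linked": 1,
              "inherited_dominant": 1, "compound_het": 1, "de_novo_cnv": 1,
              "homozygous_cnv": 1, "tre_known": 1, "mtdna": 1}


def small_spec(seed=3, **kw):
    defaults = dict(n_families=25, n_background_sites=400, n_x_sites=60,
                    plant_plan=dict(SMALL_PLAN), n_recessive_in_consanguineous=2,
                    seed=seed)
    defaults.update(kw)
    return CohortSpec(**defaults)


def test_consanguineous_count_is_exact():
    spec = CohortSpec(n_families=100, consanguineous_fraction=0.44, seed=7,
                      n_background_sites=10, n_x_sites=5)
    cohort = simulate_cohort(spec)
    assert len(cohort.consanguineous_families) == 44
    # consanguineous families are emitted as ordinary trios (no hidden ids)
    for fam in cohort.pedigree.families:
        assert not any("_H" in m.sample_id for m in fam.members)


def test_zero_consanguinity_means_no_shared_founders():
    spec = small_spec(consanguineous_fraction=0.0,
                      n_recessive_in_consanguineous=0)
    cohort = simulate_cohort(spec)
    assert cohort.consanguineous_families == set()
    for fam in cohort.pedigree.families:
        parents = {m.sample_id for m in fam.members
                   if m.father_id is None and m.mother_id is None}
        # every parent is an unrelated founder
        for m in fam.members:
            if m.father_id:
                assert m.father_id in parents


def test_fixed_seed_gives_byte_identical_outputs(tmp_path):
    spec1, spec2 = small_spec(seed=11), small_spec(seed=11)
    c1 = simulate_cohort(spec1)
    c2 = simulate_cohort(spec2)
    d1, d2 = tmp_path / "a", tmp_path / "b"
    p1, p2 = c1.write(d1), c2.write(d2)
    for key in p1:
        assert p1[key].read_bytes() == p2[key].read_bytes(), key
    c3 = simulate_cohort(small_spec(seed=12))
    assert (tmp_path / "a" / "cohort.ped").read_bytes() != \
        _bytes_of(c3, tmp_path / "c")


def _bytes_of(cohort, outdir):
    cohort.write(outdir)
    return (outdir / "cohort.ped").read_bytes()


def test_trio_completeness_and_proband_structure():
    ped = simulate_pedigrees(CohortSpec(n_families=100, seed=5))
    complete = ped.complete_trio_families()
    assert len(complete) == 79
    multiplex = [f for f in ped.families
                 if sum(1 for m in f.members if m.affected) >= 3]
    assert len(multiplex) == 2


def test_plants_land_in_eligible_distinct_families():
    cohort = simulate_cohort(small_spec())
    by_scenario = {}
    for t in cohort.truth:
        by_scenario.setdefault(t.scenario, []).append(t)
    dn = by_scenario["de_novo_snv"]
    assert len({t.family_id for t in dn}) == len(dn) == 2
    for t in dn:
        fam = cohort.pedigree.family(t.family_id)
        assert any(fam.is_complete_trio(p) for p in fam.probands())
    hom = by_scenario["homozygous_recessive"]
    assert all(t.family_id in cohort.consanguineous_families for t in hom)
    for t in by_scenario["x_linked"]:
        fam = cohort.pedigree.family(t.family_id)
        assert fam.probands()[0].sex == "male"
    # all plants in distinct families
    fams = [t.family_id for t in cohort.truth]
    assert len(fams) == len(set(fams))


def test_x_linked_plant_without_male_probands_errors():
    spec = small_spec(male_proband_fraction=0.0,
                      plant_plan={"x_linked": 1})
    with pytest.raises(PlantError, match="x_linked"):
        simulate_cohort(spec)


def test_validation_errors():
    with pytest.raises(ValueError, match="consanguineous_fraction"):
        CohortSpec(consanguineous_fraction=1.5).validate()
    with pytest.raises(ValueError, match="scenario"):
        CohortSpec(plant_plan={"bogus": 1}).validate()


def test_offspring_heterozygosity_binomial_oracle():
    # single founder pair at MAF 0.5: offspring are het w.p. 0.5 per site
    fam = Family("F1", [Member("F", "male", False), Member("M", "female", False),
                        Member("C", "male", True, "F", "M")])
    n = 10_000
    spec = CohortSpec(n_families=1, n_background_sites=n, n_x_sites=2,
                      maf_range=(0.5, 0.5), seed=123)
    records = simulate_genotypes(Pedigree(families=[fam]), spec)
    geno, samples = genotype_matrix(records)
    child = geno[:, samples.index("C")]
    het_frac = float(np.mean(child == 1))
    se = np.sqrt(0.25 / n)
    assert abs(het_frac - 0.5) <= 3 * se


def test_no_mendelian_violations_without_noise():
    cohort = simulate_cohort(small_spec(genotype_error_rate=0.0))
    records = [r for r in cohort.records if r.chrom == "chr1"]
    planted_keys = set()
    for t in cohort.truth:
        planted_keys.update(t.key.split("|"))
    geno, samples = genotype_matrix(records)
    idx = {s: i for i, s in enumerate(samples)}
    keys = [r.key for r in records]
    for fam in cohort.pedigree.families:
        for child in fam.children():
            father, mother = fam.parents_of(child)
            if not father or not mother:
                continue
            c = geno[:, idx[child.sample_id]]
            f = geno[:, idx[father.sample_id]]
            m = geno[:, idx[mother.sample_id]]
            # impossible transmissions: child allele absent from a parent
            viol = ((c == 2) & ((f == 0) | (m == 0))) | \
                   ((c == 0) & ((f == 2) | (m == 2))) | \
                   ((c == 1) & (((f == 0) & (m == 0)) | ((f == 2) & (m == 2))))
            for i in np.where(viol)[0]:
                assert keys[i] in planted_keys, \
                    f"unplanted Mendelian violation at {keys[i]}"


def test_planted_cnvs_without_noise_are_identical_across_callers():
    cohort = simulate_cohort(small_spec(cnv_jitter=0, cnv_fp_rate=0.0))
    truth_cnvs = [t for t in cohort.truth if t.scenario.endswith("_cnv")]
    for t in truth_cnvs:
        chrom, span, cnv_type = t.key.split(":")
        start, end = map(int, span.split("-"))
        seen = {caller for caller, calls in cohort.cnv_callsets.items()
                for c in calls if (c.start, c.end, c.type) == (start, end, cnv_type)}
        assert len(seen) == cohort.spec.cnv_callers_per_plant
    # no calls anywhere else
    total = sum(len(c) for c in cohort.cnv_callsets.values())
    carriers = {"de_novo_cnv": 1, "homozygous_cnv": 3}
    expected = sum(carriers[t.scenario] * cohort.spec.cnv_callers_per_plant
                   for t in truth_cnvs)
    assert total == expected


def test_planted_sites_pass_qc_and_rarity_by_construction():
    from famvarkit.snv_prioritizer import qc_filter, rarity_filter
    cohort = simulate_cohort(small_spec())
    planted_keys = set()
    for t in cohort.truth:
        if t.scenario in {"de_novo_snv", "inherited_dominant",
                          "homozygous_recessive", "x_linked", "compound_het"}:
            planted_keys.update(t.key.split("|"))
    kept = rarity_filter(qc_filter(list(cohort.records),
                                   pedigree=cohort.pedigree))
    kept_keys = {r.key for r in kept}
    assert planted_keys <= kept_keys
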