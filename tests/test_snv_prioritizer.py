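"""QC, rarity, impact voting, inheritance rules, and tiering."""

import itertools

import numpy as np
import pytest

from conftest import DAMAGING, brute_force_snv_candidates, make_record, make_trio
from famvarkit.config import Thresholds
from famvarkit.io_formats import (ConstraintScores, Pedigree, PredictorProfile,
                                  constraint_index, panel_index, PanelEntry)
from famvarkit.snv_prioritizer import (CandidateVariant, classify_impact,
                                       classify_inheritance, find_compound_hets,
                                       predictor_votes, prioritize, qc_filter,
                                       rarity_filter, tier_candidates)

TH = Thresholds()


# ---------------------------------------------------------------------------
# QC
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("call,expected", [
    ((1, 35, 40, 20, 20), True),    # balanced het
    ((1, 35, 100, 81, 19), False),  # allele balance 0.19 < 0.2
    ((1, 35, 100, 80, 20), True),   # exactly 0.2: inclusive
    ((1, 35, 100, 20, 80), True),   # exactly 0.8: inclusive
    ((1, 35, 100, 19, 81), False),  # 0.81 > 0.8
    ((2, 50, 40, 0, 40), True),     # hom-alt: balance rule not applied
    ((1, 9, 40, 20, 20), False),    # GQ below 10
    ((1, 10, 19, 10, 9), False),    # depth below 20
    ((None, 99, 40, 20, 20), False),  # missing genotype excluded
    ((1, 99, 0, 0, 0), False),      # zero depth fails (with a warning)
])
def test_genotype_qc_verdicts(call, expected, recwarn):
    rec = make_record({"S1": call})
    kept = qc_filter([rec])
    assert bool(rec.qc_pass[0]) is expected
    assert bool(kept) is expected


def test_qc_site_level_criteria():
    rec = make_record({"S1": 1}, filter_status="LowQual")
    assert not qc_filter([rec])
    rec = make_record({"S1": 1}, in_lcr=True)
    assert not qc_filter([rec])


def test_qc_hemizygous_male_x_exempt_from_balance_rule():
    fam = make_trio("F1", proband_sex="male")
    ped = Pedigree(families=[fam])
    rec = make_record({"F1_P1": (1, 99, 40, 0, 40), "F1_M": (1, 99, 40, 20, 20),
                       "F1_F": 0}, chrom="chrX", pos=5_000_000)
    qc_filter([rec], pedigree=ped)
    assert rec.qc_pass[rec.genotypes.index("F1_P1")]    # hemizygous, full-alt
    assert rec.qc_pass[rec.genotypes.index("F1_M")]     # ordinary het
    # without the pedigree the proband call would look like a skewed het
    rec2 = make_record({"F1_P1": (1, 99, 40, 0, 40)}, chrom="chrX",
                       pos=5_000_000)
    qc_filter([rec2])
    assert not rec2.qc_pass[0]


def test_qc_is_per_sample():
    rec = make_record({"C": (1, 99, 40, 20, 20), "F": (0, 5, 40, 40, 0)})
    qc_filter([rec])
    assert rec.qc_pass[rec.genotypes.index("C")]
    assert not rec.qc_pass[rec.genotypes.index("F")]


# ---------------------------------------------------------------------------
# rarity
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("afs,kept", [
    ({"gnomad": 0.0005, "qgp": 0.002}, True),
    ({"gnomad": 0.0005, "qgp": 0.02}, False),   # one database over is enough
    ({"gnomad": 0.01}, False),                   # strict <
    ({"gnomad": 0.009999}, True),
    ({}, True),                                  # all missing -> treated as 0
    ({"gnomad": None, "internal": 0.001}, True),
])
def test_rarity_filter(afs, kept):
    rec = make_record({"S1": 1}, pop_afs=afs)
    assert bool(rarity_filter([rec])) is kept


# ---------------------------------------------------------------------------
# impact
# ---------------------------------------------------------------------------

def test_dmiss_requires_five_votes():
    five = PredictorProfile(cadd_phred=25.0, sift="deleterious",
                            pph2_hdiv="possibly_damaging",
                            pph2_hvar="probably_damaging", lrt="deleterious")
    rec = make_record({"S1": 1}, predictors=five)
    assert classify_impact(rec) == ("Dmiss", 5)

    four = PredictorProfile(cadd_phred=25.0, sift="deleterious",
                            pph2_hdiv="possibly_damaging",
                            pph2_hvar="probably_damaging")
    assert classify_impact(make_record({"S1": 1}, predictors=four)) == (None, 4)


def test_cadd_vote_fails_below_threshold():
    # CADD 9.9 does not vote: only 4 of the needed 5
    p = PredictorProfile(cadd_phred=9.9, sift="deleterious",
                         pph2_hdiv="probably_damaging",
                         pph2_hvar="probably_damaging", lrt="deleterious")
    rec = make_record({"S1": 1}, predictors=p)
    assert classify_impact(rec) == (None, 4)
    p10 = PredictorProfile(cadd_phred=10.0, sift="deleterious",
                           pph2_hdiv="probably_damaging",
                           pph2_hvar="probably_damaging", lrt="deleterious")
    assert classify_impact(make_record({"S1": 1}, predictors=p10))[0] == "Dmiss"


def test_mpc_vote_threshold_and_missing_votes():
    assert predictor_votes(PredictorProfile(mpc=1.0)) == 1
    assert predictor_votes(PredictorProfile(mpc=0.99)) == 0
    assert predictor_votes(PredictorProfile()) == 0   # all missing: no votes


@pytest.mark.parametrize("consequence", ["stop_gained", "frameshift_insertion",
                                         "frameshift_deletion",
                                         "splice_acceptor", "splice_donor"])
def test_lof_consequences(consequence):
    rec = make_record({"S1": 1}, consequence=consequence,
                      predictors=PredictorProfile())
    assert classify_impact(rec)[0] == "LoF"


def test_non_missense_never_dmiss():
    rec = make_record({"S1": 1}, consequence="other", predictors=DAMAGING)
    assert classify_impact(rec)[0] is None


# ---------------------------------------------------------------------------
# inheritance
# ---------------------------------------------------------------------------

def _labels(rec, fam, dominant_panel=frozenset()):
    qc_filter([rec], pedigree=Pedigree(families=[fam]))
    return classify_inheritance(rec, fam, dominant_panel)


def test_de_novo_in_complete_trio():
    fam = make_trio("F1")
    rec = make_record({"F1_P1": 1, "F1_F": 0, "F1_M": 0})
    assert set(_labels(rec, fam)) == {"de_novo"}


def test_de_novo_needs_both_parents():
    fam = make_trio("F1", father=False)
    rec = make_record({"F1_P1": 1, "F1_M": 0})
    assert "de_novo" not in _labels(rec, fam)


def test_de_novo_requires_parent_qc():
    fam = make_trio("F1")
    rec = make_record({"F1_P1": 1, "F1_F": (0, 5, 40, 40, 0), "F1_M": 0})
    assert "de_novo" not in _labels(rec, fam)


def test_homozygous_recessive_trio():
    fam = make_trio("F1")
    rec = make_record({"F1_P1": 2, "F1_F": 1, "F1_M": 1})
    assert set(_labels(rec, fam)) == {"homozygous_recessive"}


def test_homozygous_blocked_by_unaffected_hom_sibling():
    fam = make_trio("F1", unaffected_sibs=1)
    rec = make_record({"F1_P1": 2, "F1_F": 1, "F1_M": 1, "F1_S1": 2})
    assert "homozygous_recessive" not in _labels(rec, fam)
    rec2 = make_record({"F1_P1": 2, "F1_F": 1, "F1_M": 1, "F1_S1": 1})
    assert "homozygous_recessive" in _labels(rec2, fam)


def test_x_linked_male_proband():
    fam = make_trio("F1", proband_sex="male")
    rec = make_record({"F1_P1": (1, 99, 40, 0, 40), "F1_M": 1, "F1_F": 0},
                      chrom="chrX", pos=5_000_000)
    assert set(_labels(rec, fam)) == {"x_linked_recessive"}


def test_x_linked_excludes_par_and_carrier_father():
    fam = make_trio("F1", proband_sex="male")
    in_par = make_record({"F1_P1": (1, 99, 40, 0, 40), "F1_M": 1, "F1_F": 0},
                         chrom="chrX", pos=100_000)   # inside PAR1
    assert "x_linked_recessive" not in _labels(in_par, fam)
    carrier_father = make_record(
        {"F1_P1": (1, 99, 40, 0, 40), "F1_M": 1,
         "F1_F": (1, 99, 40, 0, 40)}, chrom="chrX", pos=5_000_000)
    assert "x_linked_recessive" not in _labels(carrier_father, fam)


def test_x_linked_female_proband_not_called():
    fam = make_trio("F1", proband_sex="female")
    rec = make_record({"F1_P1": 1, "F1_M": 1, "F1_F": 0},
                      chrom="chrX", pos=5_000_000)
    assert "x_linked_recessive" not in _labels(rec, fam)


def test_inherited_dominant_multiplex_segregation():
    fam = make_trio("F1", affected_sibs=2)
    rec = make_record({"F1_P1": 1, "F1_P2": 1, "F1_P3": 1,
                       "F1_F": 1, "F1_M": 0})
    labels = _labels(rec, fam)
    assert set(labels["inherited_dominant"]) == {"F1_P1", "F1_P2", "F1_P3"}


def test_inherited_dominant_needs_panel_or_segregation():
    fam = make_trio("F1")
    rec = make_record({"F1_P1": 1, "F1_F": 1, "F1_M": 0}, gene="G1")
    assert "inherited_dominant" not in _labels(rec, fam)
    assert "inherited_dominant" in _labels(rec, fam, frozenset({"G1"}))


# ---------------------------------------------------------------------------
# compound heterozygotes
# ---------------------------------------------------------------------------

def test_compound_het_trans_configuration():
    fam = make_trio("F1")
    v1 = make_record({"F1_P1": 1, "F1_F": 1, "F1_M": 0}, pos=100, gene="G")
    v2 = make_record({"F1_P1": 1, "F1_F": 0, "F1_M": 1}, pos=200, gene="G")
    qc_filter([v1, v2])
    pairs = find_compound_hets([v1, v2], fam)
    assert len(pairs) == 1
    pa, ma, proband = pairs[0]
    assert (pa.pos, ma.pos, proband) == (100, 200, "F1_P1")


def test_compound_het_cis_and_ambiguous_excluded():
    fam = make_trio("F1")
    v1 = make_record({"F1_P1": 1, "F1_F": 1, "F1_M": 0}, pos=100, gene="G")
    v2 = make_record({"F1_P1": 1, "F1_F": 1, "F1_M": 0}, pos=200, gene="G")
    qc_filter([v1, v2])
    assert find_compound_hets([v1, v2], fam) == []   # both paternal: cis
    v3 = make_record({"F1_P1": 1, "F1_F": 1, "F1_M": 1}, pos=300, gene="G")
    qc_filter([v3])
    assert find_compound_hets([v1, v3], fam) == []   # v3 ambiguous


def test_compound_het_pairs_match_exhaustive_enumeration():
    fam = make_trio("F1")
    recs = [
        make_record({"F1_P1": 1, "F1_F": 1, "F1_M": 0}, pos=100, gene="G"),
        make_record({"F1_P1": 1, "F1_F": 1, "F1_M": 0}, pos=200, gene="G"),
        make_record({"F1_P1": 1, "F1_F": 0, "F1_M": 1}, pos=300, gene="G"),
    ]
    qc_filter(recs)
    pairs = find_compound_hets(recs, fam)
    # oracle: every (paternal, maternal) combination
    expected = set()
    for a, b in itertools.permutations(recs, 2):
        pa_only = a.genotypes.call("F1_F").allele_count >= 1 \
            and a.genotypes.call("F1_M").allele_count == 0
        ma_only = b.genotypes.call("F1_M").allele_count >= 1 \
            and b.genotypes.call("F1_F").allele_count == 0
        if pa_only and ma_only:
            expected.add((a.pos, b.pos))
    assert {(p.pos, m.pos) for p, m, _ in pairs} == expected
    assert len(pairs) == 2   # two paternal x one maternal


# ---------------------------------------------------------------------------
# tiering
# ---------------------------------------------------------------------------

def _cand(rec, inheritance, impact="Dmiss"):
    return CandidateVariant(variant=rec, family_id="F1", proband_ids=["F1_P1"],
                            impact=impact, inheritance=inheritance)


PANEL = panel_index([PanelEntry("SCN2A", "dominant"),
                     PanelEntry("KDM5B", "biallelic")])
CONSTRAINTS = constraint_index([
    ConstraintScores("SCN2A", pli=1.0, prec=0.1),
    ConstraintScores("NOVELHI", pli=0.99, prec=0.96),
    ConstraintScores("NOVELLO", pli=0.2, prec=0.5)])
RECURRENCE = {"NOVELHI": 2}


def test_panel_gene_is_known_tier_regardless_of_moi():
    rec = make_record({"F1_P1": 1}, gene="KDM5B")
    tiered = tier_candidates([_cand(rec, "de_novo")], PANEL, CONSTRAINTS, {})
    assert tiered[0].tier == "known_panel"
    assert tiered[0].moi_of_panel_match == "biallelic"


def test_novel_homozygous_needs_high_prec():
    hi = make_record({"F1_P1": 2}, gene="NOVELHI")
    lo = make_record({"F1_P1": 2}, gene="NOVELLO")
    nowhere = make_record({"F1_P1": 2}, gene="UNSCORED")
    tiered = tier_candidates(
        [_cand(hi, "homozygous_recessive"), _cand(lo, "homozygous_recessive"),
         _cand(nowhere, "homozygous_recessive")],
        PANEL, CONSTRAINTS, RECURRENCE)
    assert [c.variant.gene for c in tiered] == ["NOVELHI"]
    assert tiered[0].tier == "novel_candidate"
    assert tiered[0].prec == pytest.approx(0.96)
    assert tiered[0].recurrence_support == 2


def test_novel_de_novo_keeps_pli_and_drops_other_classes():
    dn = make_record({"F1_P1": 1}, gene="NOVELHI", consequence="stop_gained",
                     predictors=PredictorProfile())
    xl = make_record({"F1_P1": 1}, gene="NOVELHI")
    tiered = tier_candidates(
        [_cand(dn, "de_novo", impact="LoF"), _cand(xl, "x_linked_recessive")],
        PANEL, CONSTRAINTS, RECURRENCE)
    assert len(tiered) == 1
    assert tiered[0].inheritance == "de_novo"
    assert tiered[0].pli == pytest.approx(0.99)


# ---------------------------------------------------------------------------
# cascade invariants
# ---------------------------------------------------------------------------

def _random_records(rng, n=60):
    samples = ["F1_F", "F1_M", "F1_P1", "F1_S1"]
    recs = []
    for i in range(n):
        genotypes = {}
        for s in samples:
            ac = int(rng.integers(0, 3)) if rng.random() > 0.05 else None
            gq = int(rng.integers(0, 100))
            dp = int(rng.integers(0, 60))
            ad_alt = int(rng.integers(0, dp + 1))
            genotypes[s] = (ac, gq, dp, dp - ad_alt, ad_alt)
        votes = int(rng.integers(0, 10))
        preds = PredictorProfile(
            cadd_phred=25.0 if votes > 0 else 5.0,
            sift="deleterious" if votes > 1 else "tolerated",
            pph2_hdiv="probably_damaging" if votes > 2 else "benign",
            pph2_hvar="possibly_damaging" if votes > 3 else "benign",
            lrt="deleterious" if votes > 4 else "neutral",
            mutation_assessor="medium" if votes > 5 else "low",
            mutation_taster="deleterious" if votes > 6 else "polymorphism",
            mpc=1.5 if votes > 7 else 0.2,
            provean="deleterious" if votes > 8 else "neutral")
        recs.append(make_record(
            genotypes, pos=1000 + i,
            consequence=str(rng.choice(["missense", "stop_gained", "other"])),
            gene=str(rng.choice(["SCN2A", "NOVELHI", "NOVELLO", "PLAIN"])),
            pop_afs={"gnomad": float(rng.choice([0.0, 0.001, 0.02, 0.2]))},
            predictors=preds,
            filter_status=str(rng.choice(["PASS", "PASS", "PASS", "LowQual"]))))
    return recs


def test_filter_order_independence(rng):
    recs = _random_records(rng)
    a = {r.key for r in rarity_filter(qc_filter([_copy(r) for r in recs]))}
    b = {r.key for r in qc_filter(rarity_filter([_copy(r) for r in recs]))}
    assert a == b


def _copy(rec):
    import copy
    new = copy.copy(rec)
    new.qc_pass = None
    return new


def test_monotonicity_in_maf_and_vote_thresholds(rng):
    recs = _random_records(rng)
    kept_tight = {r.key for r in rarity_filter(recs, threshold=0.01)}
    kept_loose = {r.key for r in rarity_filter(recs, threshold=0.05)}
    assert kept_tight <= kept_loose

    th5, th4 = Thresholds(), Thresholds(dmiss_votes_min=4)
    d5 = {r.key for r in recs if classify_impact(r, th5)[0] is not None}
    d4 = {r.key for r in recs if classify_impact(r, th4)[0] is not None}
    assert d5 <= d4


def test_every_de_novo_candidate_absent_in_parents(rng):
    ped = Pedigree(families=[make_trio("F1", unaffected_sibs=1)])
    cands = prioritize(_random_records(rng, n=120), ped, PANEL, CONSTRAINTS,
                       RECURRENCE)
    for c in cands:
        if c.inheritance == "de_novo":
            fam = ped.family(c.family_id)
            proband = fam.member(c.proband_ids[0])
            father, mother = fam.parents_of(proband)
            assert c.variant.genotypes.call(father.sample_id).allele_count == 0
            assert c.variant.genotypes.call(mother.sample_id).allele_count == 0


def test_prioritize_matches_brute_force_on_toy_cohorts(rng):
    """Oracle equivalence: the vectorized cascade agrees with a plain
    per-call re-derivation of every rule on randomized small cohorts."""
    from conftest import make_trio
    for trial in range(8):
        fams = [make_trio("F1", unaffected_sibs=1),
                make_trio("F2", proband_sex="male"),
                make_trio("F3", father=False),
                make_trio("F4", affected_sibs=2),
                make_trio("F5", proband_sex="male")]
        ped = Pedigree(families=fams)
        samples = [m.sample_id for f in fams for m in f.members]
        recs = []
        for i in range(50):
            genotypes = {}
            for s in samples:
                ac = int(rng.integers(0, 3)) if rng.random() > 0.05 else None
                gq = int(rng.integers(0, 100))
                dp = int(rng.integers(5, 60))
                ad_alt = int(rng.integers(0, dp + 1))
                genotypes[s] = (ac, gq, dp, dp - ad_alt, ad_alt)
            chrom = "chrX" if rng.random() < 0.3 else "chr1"
            recs.append(make_record(
                genotypes, chrom=chrom,
                pos=int(rng.integers(3_000_000, 9_000_000)) if chrom == "chrX"
                else 1000 + i,
                consequence=str(rng.choice(["missense", "stop_gained", "other"])),
                gene=str(rng.choice(["SCN2A", "KDM5B", "NOVELHI", "NOVELLO"])),
                pop_afs={"gnomad": float(rng.choice([0.0, 0.001, 0.02]))},
                predictors=DAMAGING if rng.random() < 0.6
                else PredictorProfile(),
                filter_status=str(rng.choice(["PASS", "PASS", "LowQual"]))))
        expected = brute_force_snv_candidates(
            [_copy(r) for r in recs], ped, PANEL, CONSTRAINTS, RECURRENCE)
        got = {(c.family_id, c.variant.key, c.inheritance, c.tier)
               for c in prioritize([_copy(r) for r in recs], ped, PANEL,
                                   CONSTRAINTS, RECURRENCE)}
        assert got == expected, f"trial {trial}"
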