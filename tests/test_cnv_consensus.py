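"""CNV consensus merging, inheritance, and known-gene/TRE overlap."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from conftest import brute_force_clusters, make_trio
from famvarkit.cnv_consensus import (CnvCall, ConsensusCnv, TreLocus,
                                     _single_linkage_clusters, cnv_inheritance,
                                     consensus_and_merge, overlap_known,
                                     reciprocal_overlap, tre_overlap)
from famvarkit.config import Thresholds


def _call(sample, start, end, cnv_type="DEL", caller="a", chrom="chr1"):
    return CnvCall(sample_id=sample, chrom=chrom, start=start, end=end,
                   type=cnv_type, caller=caller)


def test_two_callers_within_window_merge():
    sets = {"a": [_call("S1", 10_000, 20_000, caller="a")],
            "b": [_call("S1", 10_300, 20_400, caller="b")]}
    merged = consensus_and_merge(sets, window=500)
    assert len(merged) == 1
    cnv = merged[0]
    assert cnv.callers == {"a", "b"}
    assert cnv.start == 10_150 and cnv.end == 20_200   # per-endpoint medians
    assert cnv.sample_ids == {"S1"}


def test_beyond_window_or_single_caller_dropped():
    sets = {"a": [_call("S1", 10_000, 20_000, caller="a")],
            "b": [_call("S1", 10_600, 20_000, caller="b")]}
    assert consensus_and_merge(sets, window=500) == []
    solo = {"a": [_call("S1", 10_000, 20_000, caller="a")]}
    assert consensus_and_merge(solo, window=500) == []


def test_mixed_types_never_merge():
    sets = {"a": [_call("S1", 10_000, 20_000, "DEL", "a")],
            "b": [_call("S1", 10_000, 20_000, "DUP", "b")]}
    assert consensus_and_merge(sets, window=500) == []


def test_population_stage_merges_across_samples():
    sets = {"a": [_call("S1", 10_000, 20_000, caller="a"),
                  _call("S2", 10_100, 20_100, caller="a")],
            "b": [_call("S1", 10_050, 20_050, caller="b"),
                  _call("S2", 10_150, 20_150, caller="b")]}
    merged = consensus_and_merge(sets, window=500)
    assert len(merged) == 1
    assert merged[0].sample_ids == {"S1", "S2"}


def test_negative_window_rejected():
    with pytest.raises(ValueError):
        consensus_and_merge({}, window=-1)


def test_merge_idempotent_and_order_independent(rng):
    calls = []
    for caller in ("a", "b", "c"):
        for _ in range(30):
            start = int(rng.integers(0, 50_000))
            calls.append(_call(f"S{int(rng.integers(1, 4))}", start,
                               start + int(rng.integers(100, 5_000)),
                               "DEL" if rng.random() < 0.5 else "DUP", caller))
    sets = {c: [x for x in calls if x.caller == c] for c in ("a", "b", "c")}
    merged = consensus_and_merge(sets, window=500)

    # order independence
    shuffled = {c: list(reversed(v)) for c, v in reversed(sets.items())}
    merged2 = consensus_and_merge(shuffled, window=500)
    key = lambda c: (c.chrom, c.start, c.end, c.type, frozenset(c.sample_ids),
                     frozenset(c.callers))
    assert sorted(map(key, merged)) == sorted(map(key, merged2))

    # idempotence: re-merging the consensus changes nothing
    again_sets = {}
    for c in merged:
        for caller in c.callers:
            for sid in c.sample_ids:
                again_sets.setdefault(caller, []).append(
                    _call(sid, c.start, c.end, c.type, caller))
    again = consensus_and_merge(again_sets, window=500)
    assert sorted((c.chrom, c.start, c.end, c.type) for c in again) == \
        sorted(set((c.chrom, c.start, c.end, c.type) for c in merged))

    # no cluster violates the caller floor or mixes types
    for c in merged:
        assert len(c.callers) >= 2


def test_single_linkage_matches_brute_force_closure(rng):
    """200 random trials of <= 50 intervals: union-find scan == explicit
    adjacency + BFS transitive closure."""
    for _ in range(200):
        n = int(rng.integers(1, 51))
        intervals = []
        for _ in range(n):
            s = int(rng.integers(0, 3_000))
            intervals.append((s, s + int(rng.integers(1, 2_000))))
        window = int(rng.integers(0, 800))
        got = {frozenset(c) for c in _single_linkage_clusters(intervals, window)}
        assert got == brute_force_clusters(intervals, window)


@settings(max_examples=60, deadline=None, derandomize=True)
@given(st.lists(st.tuples(st.integers(0, 2000), st.integers(1, 1500)),
                min_size=1, max_size=12),
       st.integers(0, 600))
def test_single_linkage_closure_property(raw, window):
    intervals = [(s, s + length) for s, length in raw]
    got = {frozenset(c) for c in _single_linkage_clusters(intervals, window)}
    assert got == brute_force_clusters(intervals, window)


# ---------------------------------------------------------------------------
# inheritance
# ---------------------------------------------------------------------------

def _consensus(samples, start=10_000, end=20_000, cnv_type="DEL", af=None):
    return ConsensusCnv(chrom="chr1", start=start, end=end, type=cnv_type,
                        sample_ids=set(samples), callers={"a", "b"}, af=af)


def test_proband_only_rare_deletion_is_de_novo():
    fam = make_trio("F1")
    out = cnv_inheritance([_consensus({"F1_P1"})], fam)
    assert out[0].inheritance == "de_novo"


def test_de_novo_blocked_by_reference_af():
    fam = make_trio("F1")
    out = cnv_inheritance([_consensus({"F1_P1"}, af=0.002)], fam)
    assert out == []   # 0.2% >= 0.1% cutoff: too common for de novo


def test_biparental_deletion_is_homozygous_below_one_percent():
    fam = make_trio("F1")
    cnv = _consensus({"F1_P1", "F1_F", "F1_M"}, af=0.004)
    out = cnv_inheritance([cnv], fam)
    assert out[0].inheritance == "homozygous"
    common = _consensus({"F1_P1", "F1_F", "F1_M"}, af=0.02)
    assert cnv_inheritance([common], fam)[0].inheritance == "inherited"
    dup = _consensus({"F1_P1", "F1_F", "F1_M"}, cnv_type="DUP", af=0.004)
    assert cnv_inheritance([dup], fam)[0].inheritance == "inherited"


def test_single_parent_carrier_is_inherited():
    fam = make_trio("F1")
    out = cnv_inheritance([_consensus({"F1_P1", "F1_M"})], fam)
    assert out[0].inheritance == "inherited"


def test_incomplete_trio_cannot_call_de_novo():
    fam = make_trio("F1", father=False)
    assert cnv_inheritance([_consensus({"F1_P1"})], fam) == []


def test_reference_af_matching_requires_reciprocal_overlap():
    fam = make_trio("F1")
    cnv = _consensus({"F1_P1"}, start=10_000, end=20_000)
    # same type, 50% reciprocal overlap -> af matched, de novo blocked
    ref = [("chr1", 12_000, 22_000, "DEL", 0.05)]
    assert cnv_inheritance([cnv], fam, af_reference=ref) == []
    # tiny overlap -> no match, af treated as absent
    ref2 = [("chr1", 19_500, 60_000, "DEL", 0.05)]
    out = cnv_inheritance([cnv], fam, af_reference=ref2)
    assert out[0].inheritance == "de_novo"
    assert reciprocal_overlap((10_000, 20_000), (19_500, 60_000)) < 0.5


# ---------------------------------------------------------------------------
# known overlap / TREs
# ---------------------------------------------------------------------------

KNOWN = [("chr1", 100_000, 200_000, "REGION_A"),
         ("chr2", 5_000, 9_000, "GENE_B")]


def test_any_basepair_overlap_labels_known():
    spanning = _consensus({"S"}, start=90_000, end=100_000)
    short = _consensus({"S"}, start=90_000, end=99_999)   # 1 bp short
    labelled = overlap_known([spanning, short], KNOWN)
    assert labelled[0].known_label == "known"
    assert labelled[0].overlapped == ["REGION_A"]
    assert labelled[1].known_label == "novel"
    assert labelled[1].overlapped == []


def test_tre_matching_and_gene_count():
    genes = [("chr1", 1_000 + 100 * j, 1_050 + 100 * j, f"G{j}")
             for j in range(57)]
    inside = TreLocus("chr1", 1_010, 1_030, "AAAAT", carriers={"S1"})
    off_chrom = TreLocus("chr9", 1_010, 1_030, "CAG", carriers={"S2"})
    matches = tre_overlap([inside, off_chrom], genes)
    assert tre_overlap.last_n_genes == 57
    assert len(matches) == 1
    locus, hit_genes = matches[0]
    assert hit_genes == ["G0"] and locus.carriers == {"S1"}


# ---------------------------------------------------------------------------
# planted recovery under noise
# ---------------------------------------------------------------------------

def test_planted_cnv_recovery_with_jitter_and_false_positives():
    """Jitter <= 250 bp and caller false positives: every plant is
    recovered, every single-caller artifact removed."""
    from famvarkit.synthetic_cohort import CohortSpec, simulate_cohort
    spec = CohortSpec(n_families=30, n_background_sites=50, n_x_sites=10,
                      cnv_jitter=250, cnv_fp_rate=0.2,
                      plant_plan={"de_novo_cnv": 1, "homozygous_cnv": 1},
                      seed=42)
    cohort = simulate_cohort(spec)
    merged = consensus_and_merge(cohort.cnv_callsets, window=500)
    truth = [t for t in cohort.truth if t.scenario.endswith("_cnv")]
    assert len(merged) == len(truth)   # all false positives removed
    for t in truth:
        chrom, span, cnv_type = t.key.split(":")
        start, end = map(int, span.split("-"))
        assert any(c.chrom == chrom and c.type == cnv_type
                   and abs(c.start - start) <= 250 and abs(c.end - end) <= 250
                   for c in merged), t
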