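"""Shared builders for hand-crafted records, families, and oracles."""

from __future__ import annotations

from math import comb
from typing import Dict, Optional, Tuple

import numpy as np
import pytest

from famvarkit.io_formats import (Family, GenotypeCall, GenotypeTable, Member,
                                  Pedigree, PredictorProfile, VariantRecord)

DAMAGING = PredictorProfile(
    cadd_phred=25.0, sift="deleterious", pph2_hdiv="probably_damaging",
    pph2_hvar="probably_damaging", lrt="deleterious",
    mutation_assessor="high", mutation_taster="deleterious",
    mpc=1.8, provean="deleterious")


def make_record(genotypes: Dict[str, Tuple],
                chrom: str = "chr1", pos: int = 1000, ref: str = "A",
                alt: str = "G", consequence: str = "missense",
                gene: Optional[str] = "GENE1",
                pop_afs: Optional[Dict[str, float]] = None,
                predictors: PredictorProfile = DAMAGING,
                filter_status: str = "PASS", in_lcr: bool = False,
                acmg: Optional[str] = None) -> VariantRecord:
    """Build a record from ``{sample: (ac, gq, dp, ad_ref, ad_alt)}``.

    A 2-tuple ``(ac, None)`` or bare int ac is padded with clean QC
    metrics (GQ 99, DP 40, balanced AD).
    """
    calls = []
    for sid, spec in genotypes.items():
        if isinstance(spec, int) or spec is None:
            ac = spec
            gq, dp = 99, 40
            ad_alt = {None: 0, 0: 0, 1: 20, 2: 40}[ac]
            calls.append(GenotypeCall(sid, ac, gq, dp, 40 - ad_alt, ad_alt))
        else:
            ac, gq, dp, ad_ref, ad_alt = spec
            calls.append(GenotypeCall(sid, ac, gq, dp, ad_ref, ad_alt))
    return VariantRecord(
        chrom=chrom, pos=pos, ref=ref, alt=alt, filter_status=filter_status,
        consequence=consequence, gene=gene, pop_afs=dict(pop_afs or {}),
        predictors=predictors, acmg_label=acmg,
        genotypes=GenotypeTable.from_calls(calls), in_lcr=in_lcr)


def make_trio(family_id: str = "F1", proband_sex: str = "male",
              father: bool = True, mother: bool = True,
              unaffected_sibs: int = 0, affected_sibs: int = 0) -> Family:
    members = []
    fid, mid = f"{family_id}_F", f"{family_id}_M"
    if father:
        members.append(Member(fid, "male", False))
    if mother:
        members.append(Member(mid, "female", False))
    members.append(Member(f"{family_id}_P1", proband_sex, True,
                          fid if father else None, mid if mother else None))
    for k in range(affected_sibs):
        members.append(Member(f"{family_id}_P{k + 2}", "male", True,
                              fid if father else None, mid if mother else None))
    for k in range(unaffected_sibs):
        members.append(Member(f"{family_id}_S{k + 1}", "female", False,
                              fid if father else None, mid if mother else None))
    return Family(family_id=family_id, members=members)


# ---------------------------------------------------------------------------
# independent oracles
# ---------------------------------------------------------------------------

def fisher_two_sided_oracle(table) -> float:
    """Exhaustive hypergeometric enumeration of the two-sided Fisher p:
    the sum of probabilities of all tables (with fixed margins) no more
    probable than the observed one."""
    (a, b), (c, d) = table
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2
    denom = comb(n, c1)

    def prob(x):
        return comb(r1, x) * comb(r2, c1 - x) / denom

    p_obs = prob(a)
    lo, hi = max(0, c1 - r2), min(r1, c1)
    return sum(prob(x) for x in range(lo, hi + 1)
               if prob(x) <= p_obs * (1 + 1e-9))


def brute_force_clusters(intervals, window):
    """Transitive closure over the pairwise within-window relation by
    explicit adjacency + BFS (independent of the union-find scan)."""
    n = len(intervals)
    adj = [[False] * n for _ in range(n)]
    for i in range(n):
        for j in range(n):
            if i != j and abs(intervals[i][0] - intervals[j][0]) <= window \
                    and abs(intervals[i][1] - intervals[j][1]) <= window:
                adj[i][j] = True
    seen = [False] * n
    clusters = []
    for s in range(n):
        if seen[s]:
            continue
        stack, comp = [s], []
        seen[s] = True
        while stack:
            u = stack.pop()
            comp.append(u)
            for v in range(n):
                if adj[u][v] and not seen[v]:
                    seen[v] = True
                    stack.append(v)
        clusters.append(frozenset(comp))
    return set(clusters)


def brute_force_snv_candidates(records, pedigree: Pedigree, panel,
                               constraints, recurrence,
                               maf_max=0.01, votes_min=5):
    """Plain re-derivation of the SNV cascade from the written rules,
    using per-call objects and explicit loops (no shared code with the
    implementation's vectorized path).  Returns a set of
    (family_id, variant key, inheritance, tier) tuples, compound hets
    included.
    """
    males = {m.sample_id for f in pedigree.families for m in f.members
             if m.sex == "male"}

    def chrx(rec):
        return rec.chrom.removeprefix("chr").upper() == "X"

    def qc(rec, sid):
        call = rec.genotypes.call(sid)
        if call.allele_count is None:
            return False
        if rec.filter_status != "PASS" or rec.in_lcr:
            return False
        if call.gq is None or call.gq < 10:
            return False
        if call.dp is None or call.dp < 20:
            return False
        hemi = chrx(rec) and sid in males and call.allele_count == 1
        if call.allele_count == 1 and not hemi:
            if call.ad_ref is None or call.ad_alt is None:
                return False
            total = call.ad_ref + call.ad_alt
            if total == 0:
                return False
            ab = call.ad_alt / total
            if not (0.2 <= ab <= 0.8):
                return False
        return True

    def rare(rec):
        return all((af or 0.0) < maf_max for af in rec.pop_afs.values())

    def votes(p):
        v = 0
        if p.cadd_phred is not None and p.cadd_phred >= 10:
            v += 1
        if p.sift == "deleterious":
            v += 1
        if p.pph2_hdiv in ("probably_damaging", "possibly_damaging"):
            v += 1
        if p.pph2_hvar in ("probably_damaging", "possibly_damaging"):
            v += 1
        if p.lrt == "deleterious":
            v += 1
        if p.mutation_assessor in ("high", "medium"):
            v += 1
        if p.mutation_taster == "deleterious":
            v += 1
        if p.mpc is not None and p.mpc >= 1:
            v += 1
        if p.provean == "deleterious":
            v += 1
        return v

    def impact(rec):
        lof = {"stop_gained", "frameshift_insertion", "frameshift_deletion",
               "splice_acceptor", "splice_donor"}
        if rec.consequence in lof:
            return "LoF"
        if rec.consequence == "missense" and votes(rec.predictors) >= votes_min:
            return "Dmiss"
        return None

    def ac(rec, sid):
        if sid is None or sid not in rec.genotypes:
            return None
        return rec.genotypes.call(sid).allele_count

    dominant_panel = {g for g, mois in panel.items() if "dominant" in mois}
    damaging = [(r, impact(r)) for r in records
                if any(qc(r, s) for s in r.genotypes.samples)
                and rare(r) and impact(r) is not None]

    out = set()
    for fam in pedigree.families:
        unaffected_sibs = [m for m in fam.children() if m.affected is False]
        affected = [m for m in fam.members if m.affected]
        labelled = []
        for rec, imp in damaging:
            for proband in fam.probands():
                pid = proband.sample_id
                p_ac = ac(rec, pid)
                if not p_ac or not qc(rec, pid):
                    continue
                father, mother = fam.parents_of(proband)
                f_ac = ac(rec, father.sample_id) if father else None
                m_ac = ac(rec, mother.sample_id) if mother else None
                if (father and mother and f_ac == 0 and m_ac == 0
                        and qc(rec, father.sample_id)
                        and qc(rec, mother.sample_id)):
                    labelled.append((rec, imp, "de_novo"))
                if not chrx(rec) and p_ac == 2:
                    ok = all(x is None or x >= 1 for x in (f_ac, m_ac))
                    blocked = any(ac(rec, s.sample_id) == 2
                                  and qc(rec, s.sample_id)
                                  for s in unaffected_sibs)
                    if ok and not blocked:
                        labelled.append((rec, imp, "homozygous_recessive"))
                if (chrx(rec) and proband.sex == "male" and p_ac == 1
                        and not (10_001 <= rec.pos <= 2_781_479
                                 or 155_701_383 <= rec.pos <= 156_030_895)):
                    if (m_ac is None or m_ac == 1) and (f_ac is None or f_ac == 0):
                        labelled.append((rec, imp, "x_linked_recessive"))
                if not chrx(rec) and p_ac == 1:
                    het_parents = sum(1 for x in (f_ac, m_ac) if x == 1)
                    shared = sum(1 for m in affected
                                 if (ac(rec, m.sample_id) or 0) >= 1
                                 and qc(rec, m.sample_id))
                    blocked = any((ac(rec, s.sample_id) or 0) >= 1
                                  and qc(rec, s.sample_id)
                                  for s in unaffected_sibs)
                    if het_parents == 1 and not blocked and (
                            shared >= 2 or (rec.gene in dominant_panel)):
                        labelled.append((rec, imp, "inherited_dominant"))
        # compound hets: complete trios, trans configuration only
        for proband in fam.probands():
            father, mother = fam.parents_of(proband)
            if father is None or mother is None:
                continue
            by_gene = {}
            for rec, imp in damaging:
                if rec.gene is None or ac(rec, proband.sample_id) != 1 \
                        or not qc(rec, proband.sample_id):
                    continue
                pa = (ac(rec, father.sample_id) or 0) >= 1
                ma = (ac(rec, mother.sample_id) or 0) >= 1
                if pa != ma:
                    by_gene.setdefault(rec.gene, []).append(
                        (rec, imp, "father" if pa else "mother"))
            for gene, items in by_gene.items():
                pat = [x for x in items if x[2] == "father"]
                mat = [x for x in items if x[2] == "mother"]
                if pat and mat:
                    for rec, imp, _ in pat + mat:
                        labelled.append((rec, imp, "compound_het"))
        # tiering
        for rec, imp, inh in labelled:
            gene = rec.gene
            if gene is not None and gene in panel:
                out.add((fam.family_id, rec.key, inh, "known_panel"))
            elif inh == "de_novo":
                out.add((fam.family_id, rec.key, inh, "novel_candidate"))
            elif inh == "homozygous_recessive":
                scores = constraints.get(gene)
                prec = getattr(scores, "prec", None)
                if prec is not None and prec > 0.9:
                    out.add((fam.family_id, rec.key, inh, "novel_candidate"))
    return out


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240917)
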