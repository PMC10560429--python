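"""QC, rarity, impact, inheritance, and tiering rules for SNVs/indels.

The filtering cascade applied per family:

1. quality control — a genotype passes iff the site is FILTER=PASS,
   GQ >= 10, DP >= 20, outside low-complexity regions, and (for
   heterozygotes only) the allele balance ad_alt/(ad_ref+ad_alt) lies in
   [0.2, 0.8];
2. rarity — retained iff allele frequency < 1% in every configured
   population database (missing = absent = 0);
3. impact — loss-of-function consequences (stop gain, frameshift
   insertion/deletion, canonical splice site) or damaging missense
   (Dmiss): deleterious votes from at least 5 of the 9 predictors at
   their stated thresholds (CADD >= 10, MPC >= 1, categorical calls as
   listed in :func:`predictor_votes`); a missing predictor never votes;
4. inheritance — de novo, homozygous recessive, X-linked recessive,
   inherited dominant, and compound heterozygous patterns evaluated
   against the pedigree with per-sample QC verdicts;
5. tiering — candidates in the known ASD/NDD panel (membership by gene
   symbol; the panel's mode of inheritance is recorded as an annotation,
   not used as a gate) versus novel candidates, where novel de novo
   events require a damaging impact and novel homozygous events
   additionally require pRec > 0.9.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass, field
from typing import Dict, FrozenSet, Iterable, List, Mapping, Optional, Sequence, Set, Tuple

import numpy as np

from .config import Thresholds, DEFAULT_CONFIG, DEFAULT_PAR
from .io_formats import (Family, GenotypeTable, Pedigree, PredictorProfile,
                         VariantRecord, LOF_CONSEQUENCES, MISSING_INT32,
                         is_chrx, constraint_index, panel_index)

log = logging.getLogger(__name__)

INHERITANCE_CLASSES = ("de_novo", "inherited_dominant", "homozygous_recessive",
                       "x_linked_recessive", "compound_het")


@dataclass(slots=True)
class CandidateVariant:
    variant: VariantRecord
    family_id: str
    proband_ids: List[str]
    impact: str                     # "LoF" | "Dmiss"
    inheritance: str
    tier: Optional[str] = None      # "known_panel" | "novel_candidate"
    moi_of_panel_match: Optional[str] = None
    pli: Optional[float] = None
    prec: Optional[float] = None
    recurrence_support: Optional[int] = None
    acmg_label: Optional[str] = None
    dmiss_votes: int = 0
    pair_id: Optional[str] = None   # shared by the two halves of a compound het


# ---------------------------------------------------------------------------
# QC
# ---------------------------------------------------------------------------

def genotype_qc_mask(record: VariantRecord,
                     thresholds: Optional[Thresholds] = None,
                     male_mask: Optional[np.ndarray] = None) -> np.ndarray:
    """Boolean per-sample QC verdict for one record.

    The allele-balance bounds are inclusive and apply to heterozygous
    calls only; an allele count of 1 on chrX in a male is hemizygous,
    not heterozygous, so ``male_mask`` (per-sample booleans from the
    pedigree) exempts those calls from the balance rule.  A zero-depth
    non-missing genotype fails.  Missing genotypes fail (they are
    excluded from every rule anyway).
    """
    th = thresholds or DEFAULT_CONFIG.thresholds
    t: GenotypeTable = record.genotypes
    ac = t.allele_count
    present = ac >= 0
    ok = present & (record.filter_status == "PASS") & (not record.in_lcr)
    gq_ok = (t.gq != MISSING_INT32) & (t.gq >= th.gq_min)
    dp_ok = (t.dp != MISSING_INT32) & (t.dp >= th.dp_min)
    ok = ok & gq_ok & dp_ok
    zero_dp = present & (t.dp != MISSING_INT32) & (t.dp == 0)
    if np.any(zero_dp):
        warnings.warn(f"{record.key}: zero-depth genotype(s) treated as failing")
    het = ac == 1
    if male_mask is not None and is_chrx(record.chrom):
        het = het & ~np.asarray(male_mask, dtype=bool)
    ad_known = (t.ad_ref != MISSING_INT32) & (t.ad_alt != MISSING_INT32)
    total = np.where(ad_known, t.ad_ref + t.ad_alt, 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        ab = np.where(total > 0, t.ad_alt / np.maximum(total, 1), np.nan)
    ab_ok = ad_known & (total > 0) & (ab >= th.ab_low) & (ab <= th.ab_high)
    ok = ok & np.where(het, ab_ok, True)
    return ok


def _male_mask(samples: Sequence[str], pedigree: Optional[Pedigree]) -> Optional[np.ndarray]:
    if pedigree is None:
        return None
    males = {m.sample_id for fam in pedigree.families
             for m in fam.members if m.sex == "male"}
    return np.array([s in males for s in samples], dtype=bool)


def qc_filter(records: Iterable[VariantRecord],
              thresholds: Optional[Thresholds] = None,
              pedigree: Optional[Pedigree] = None) -> List[VariantRecord]:
    """Annotate per-sample QC verdicts; keep records where any sample
    passes.  A site may pass in the child and fail in a parent — the
    verdicts are kept per sample on ``record.qc_pass``.  Supplying the
    pedigree lets chrX hemizygous male calls bypass the het-only
    allele-balance rule."""
    th = thresholds or DEFAULT_CONFIG.thresholds
    kept = []
    males = None
    for rec in records:
        if males is None or len(males) != len(rec.genotypes.samples):
            males = _male_mask(rec.genotypes.samples, pedigree)
        mask = genotype_qc_mask(rec, th, males)
        rec.qc_pass = mask
        if mask.any():
            kept.append(rec)
    return kept


# ---------------------------------------------------------------------------
# rarity
# ---------------------------------------------------------------------------

def rarity_filter(records: Iterable[VariantRecord],
                  threshold: Optional[float] = None) -> List[VariantRecord]:
    """Keep records with AF strictly below the threshold in every
    configured database (one failure suffices to remove; missing = 0)."""
    if threshold is None:
        threshold = DEFAULT_CONFIG.thresholds.maf_max
    return [r for r in records if r.max_pop_af() < threshold]


# ---------------------------------------------------------------------------
# impact
# ---------------------------------------------------------------------------

def predictor_votes(p: PredictorProfile,
                    thresholds: Optional[Thresholds] = None) -> int:
    """Count deleterious votes across the nine predictors."""
    th = thresholds or DEFAULT_CONFIG.thresholds
    votes = 0
    votes += p.cadd_phred is not None and p.cadd_phred >= th.cadd_min
    votes += p.sift == "deleterious"
    votes += p.pph2_hdiv in ("probably_damaging", "possibly_damaging")
    votes += p.pph2_hvar in ("probably_damaging", "possibly_damaging")
    votes += p.lrt == "deleterious"
    votes += p.mutation_assessor in ("high", "medium")
    votes += p.mutation_taster == "deleterious"
    votes += p.mpc is not None and p.mpc >= th.mpc_min
    votes += p.provean == "deleterious"
    return int(votes)


def classify_impact(record: VariantRecord,
                    thresholds: Optional[Thresholds] = None
                    ) -> Tuple[Optional[str], int]:
    """(impact, dmiss_votes): "LoF", "Dmiss", or None."""
    th = thresholds or DEFAULT_CONFIG.thresholds
    votes = predictor_votes(record.predictors, th)
    if record.consequence in LOF_CONSEQUENCES:
        return "LoF", votes
    if record.consequence == "missense" and votes >= th.dmiss_votes_min:
        return "Dmiss", votes
    return None, votes


# ---------------------------------------------------------------------------
# inheritance
# ---------------------------------------------------------------------------

def _qc_ok(record: VariantRecord, sample_id: str) -> bool:
    if record.qc_pass is None:
        return True
    t = record.genotypes
    return sample_id in t and bool(record.qc_pass[t.index(sample_id)])


def _ac(record: VariantRecord, sample_id: Optional[str]) -> Optional[int]:
    if sample_id is None or sample_id not in record.genotypes:
        return None
    return record.genotypes.allele_count_of(sample_id)


def in_par(pos: int, par_intervals=DEFAULT_PAR) -> bool:
    return any(lo <= pos <= hi for lo, hi in par_intervals)


def classify_inheritance(record: VariantRecord, family: Family,
                         dominant_panel: FrozenSet[str] = frozenset(),
                         thresholds: Optional[Thresholds] = None
                         ) -> Dict[str, List[str]]:
    """Inheritance labels for one record in one family.

    Returns label -> list of proband sample ids exhibiting it.  Labels
    are not mutually exclusive at this stage.  Rules (genotypes must
    pass QC to count; a missing or failing proband genotype yields no
    label):

    de_novo
        complete trio; proband carries ALT; both parents hom-ref with
        passing QC at the site.
    homozygous_recessive
        autosomal; proband hom-alt; every available parent carries at
        least one ALT; no QC-passing unaffected sibling hom-alt.
    x_linked_recessive
        male proband; chrX outside the pseudo-autosomal regions; proband
        hemizygous ALT; mother het if available; father non-carrier if
        available.
    inherited_dominant
        proband het; exactly one parent het; and either >= 2 affected
        members share the het genotype (multiplex segregation) or the
        gene is a dominant panel gene; no QC-passing unaffected sibling
        carries it.
    """
    th = thresholds or DEFAULT_CONFIG.thresholds
    labels: Dict[str, List[str]] = {}
    chrx = is_chrx(record.chrom)
    unaffected_sibs = [m for m in family.children() if m.affected is False]
    affected = [m for m in family.members if m.affected]

    for proband in family.probands():
        pid = proband.sample_id
        p_ac = _ac(record, pid)
        if p_ac is None or p_ac == 0 or not _qc_ok(record, pid):
            continue
        father, mother = family.parents_of(proband)
        f_ac = _ac(record, father.sample_id) if father else None
        m_ac = _ac(record, mother.sample_id) if mother else None
        f_qc = father is not None and _qc_ok(record, father.sample_id)
        m_qc = mother is not None and _qc_ok(record, mother.sample_id)

        # -- de novo: complete trios only
        if (father is not None and mother is not None
                and f_ac == 0 and m_ac == 0 and f_qc and m_qc):
            labels.setdefault("de_novo", []).append(pid)

        # -- homozygous recessive (autosomes)
        if not chrx and p_ac == 2:
            parents_carry = all(
                ac is None or ac >= 1
                for ac in (f_ac if father else None, m_ac if mother else None))
            sib_block = any(
                _ac(record, s.sample_id) == 2 and _qc_ok(record, s.sample_id)
                for s in unaffected_sibs)
            if parents_carry and not sib_block:
                labels.setdefault("homozygous_recessive", []).append(pid)

        # -- X-linked recessive (male probands, non-PAR X)
        if (chrx and proband.sex == "male"
                and not in_par(record.pos, th.par_intervals) and p_ac == 1):
            mother_ok = m_ac is None or m_ac == 1
            father_ok = f_ac is None or f_ac == 0
            if mother_ok and father_ok:
                labels.setdefault("x_linked_recessive", []).append(pid)

        # -- inherited dominant
        if p_ac == 1 and not chrx:
            het_parents = [ac for ac in (f_ac, m_ac) if ac == 1]
            if len(het_parents) == 1:
                n_affected_carriers = sum(
                    1 for m in affected
                    if _ac(record, m.sample_id) in (1, 2)
                    and _qc_ok(record, m.sample_id))
                panel_hit = record.gene is not None and record.gene in dominant_panel
                sib_block = any(
                    (_ac(record, s.sample_id) or 0) >= 1
                    and _qc_ok(record, s.sample_id)
                    for s in unaffected_sibs)
                if (n_affected_carriers >= 2 or panel_hit) and not sib_block:
                    labels.setdefault("inherited_dominant", []).append(pid)
    return labels


# ---------------------------------------------------------------------------
# compound heterozygotes
# ---------------------------------------------------------------------------

def transmitting_parents(record: VariantRecord, family: Family,
                         proband_id: str) -> Optional[Set[str]]:
    """Which parents could have transmitted the proband's het allele.

    Returns a subset of {"father", "mother"}; None when the proband is
    not a QC-passing heterozygote or the trio is incomplete.
    """
    proband = family.member(proband_id)
    father, mother = family.parents_of(proband)
    if father is None or mother is None:
        return None
    if _ac(record, proband_id) != 1 or not _qc_ok(record, proband_id):
        return None
    sources = set()
    if (_ac(record, father.sample_id) or 0) >= 1:
        sources.add("father")
    if (_ac(record, mother.sample_id) or 0) >= 1:
        sources.add("mother")
    return sources


def find_compound_hets(records: Sequence[VariantRecord], family: Family
                       ) -> List[Tuple[VariantRecord, VariantRecord, str]]:
    """Phased-by-transmission compound heterozygote pairs.

    Input records must already be QC/rarity filtered and carry a
    damaging impact.  A pair is two distinct variants in the same gene
    with the proband het at both, one unambiguously transmitted by the
    father only and the other by the mother only; variants that could
    have come from either parent are excluded.  Every qualifying
    maternal x paternal combination is returned.
    """
    pairs = []
    for proband in family.probands():
        if not family.is_complete_trio(proband):
            continue
        by_gene: Dict[str, List[Tuple[VariantRecord, Set[str]]]] = {}
        for rec in records:
            if rec.gene is None:
                continue
            sources = transmitting_parents(rec, family, proband.sample_id)
            if sources is None or len(sources) != 1:
                continue
            by_gene.setdefault(rec.gene, []).append((rec, sources))
        for gene, items in by_gene.items():
            paternal = [r for r, s in items if s == {"father"}]
            maternal = [r for r, s in items if s == {"mother"}]
            for pa, ma in itertools.product(paternal, maternal):
                pairs.append((pa, ma, proband.sample_id))
    return pairs


# ---------------------------------------------------------------------------
# tiering
# ---------------------------------------------------------------------------

def tier_candidates(candidates: Iterable[CandidateVariant],
                    panel: Mapping[str, List[str]],
                    constraints: Mapping[str, object],
                    recurrence: Mapping[str, int],
                    thresholds: Optional[Thresholds] = None
                    ) -> List[CandidateVariant]:
    """Assign the known-panel / novel-candidate tier.

    Panel membership is by gene symbol; the matched panel MOI is carried
    as an annotation only (the cohort includes de novo hits in genes
    with recessive disease associations).  Outside the panel, only de
    novo and homozygous events are eligible for the novel tier — de
    novo needs a damaging impact; homozygous additionally needs
    pRec > 0.9 (a candidate whose gene is missing from the constraint
    table is excluded and the exclusion logged).  Novel candidates are
    annotated with external-cohort recurrence support; pLI is attached
    to all de novo LoF candidates.
    """
    th = thresholds or DEFAULT_CONFIG.thresholds
    out = []
    for cand in candidates:
        gene = cand.variant.gene
        scores = constraints.get(gene) if gene else None
        cand.pli = getattr(scores, "pli", None)
        cand.prec = getattr(scores, "prec", None)
        cand.acmg_label = cand.variant.acmg_label
        if gene is not None and gene in panel:
            cand.tier = "known_panel"
            cand.moi_of_panel_match = ",".join(panel[gene])
            out.append(cand)
            continue
        if cand.inheritance == "de_novo" and cand.impact in ("LoF", "Dmiss"):
            cand.tier = "novel_candidate"
        elif cand.inheritance == "homozygous_recessive" and cand.impact in ("LoF", "Dmiss"):
            if cand.prec is None:
                log.info("novel homozygous candidate %s in %s excluded: "
                         "no pRec available", cand.variant.key, gene)
                continue
            if cand.prec > th.prec_min:
                cand.tier = "novel_candidate"
            else:
                continue
        else:
            continue
        cand.recurrence_support = recurrence.get(gene) if gene else None
        out.append(cand)
    return out


# ---------------------------------------------------------------------------
# per-family driver
# ---------------------------------------------------------------------------

def prioritize(records: Sequence[VariantRecord], pedigree: Pedigree,
               panel: Mapping[str, List[str]],
               constraints: Mapping[str, object],
               recurrence: Mapping[str, int],
               thresholds: Optional[Thresholds] = None
               ) -> List[CandidateVariant]:
    """Full SNV/indel cascade over a cohort; returns tiered candidates."""
    th = thresholds or DEFAULT_CONFIG.thresholds
    passing = qc_filter(list(records), th, pedigree)
    rare = rarity_filter(passing, th.maf_max)
    damaging: List[Tuple[VariantRecord, str, int]] = []
    for rec in rare:
        impact, votes = classify_impact(rec, th)
        if impact is not None:
            damaging.append((rec, impact, votes))

    dominant_panel = frozenset(
        g for g, mois in panel.items() if "dominant" in mois)
    candidates: List[CandidateVariant] = []
    for fam in pedigree.families:
        for rec, impact, votes in damaging:
            labels = classify_inheritance(rec, fam, dominant_panel, th)
            for label, probands in labels.items():
                candidates.append(CandidateVariant(
                    variant=rec, family_id=fam.family_id,
                    proband_ids=sorted(set(probands)), impact=impact,
                    inheritance=label, dmiss_votes=votes))
        fam_records = [rec for rec, _, _ in damaging]
        impact_of = {rec.key: (imp, v) for rec, imp, v in damaging}
        for pa, ma, proband in find_compound_hets(fam_records, fam):
            pair_id = f"{fam.family_id}:{pa.gene}:{pa.key}|{ma.key}"
            for rec in (pa, ma):
                imp, votes = impact_of[rec.key]
                candidates.append(CandidateVariant(
                    variant=rec, family_id=fam.family_id,
                    proband_ids=[proband], impact=imp,
                    inheritance="compound_het", dmiss_votes=votes,
                    pair_id=pair_id))
    return tier_candidates(candidates, panel, constraints, recurrence, th)
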