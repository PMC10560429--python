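"""Pairwise kinship, per-sample inbreeding, and consanguinity flags.

Two method-of-moments estimators over biallelic autosomal genotypes:

* the KING-robust between-family kinship coefficient

  .. math::

     \\hat\\phi = \\frac{N_{Aa,Aa} - 2 N_{AA,aa}}{2\\,\\min(N^{(i)}_{Aa}, N^{(j)}_{Aa})}
                 + \\frac12 - \\frac{N^{(i)}_{Aa} + N^{(j)}_{Aa}}
                                   {4\\,\\min(N^{(i)}_{Aa}, N^{(j)}_{Aa})}

  computed over sites non-missing in both samples, where
  :math:`N_{Aa,Aa}` counts double heterozygotes, :math:`N_{AA,aa}`
  opposite homozygotes, and :math:`N^{(k)}_{Aa}` sample *k*'s
  heterozygous sites;

* the excess-homozygosity inbreeding coefficient
  :math:`F = (O_{hom} - E_{hom}) / (n - E_{hom})` with
  :math:`E_{hom} = \\sum_i (1 - 2 p_i (1 - p_i))` from founder-based
  allele frequencies (the same convention as plink's ``--het``, without
  the small-sample correction factor).

A family is flagged consanguineous when the parental pair kinship is at
least 0.044 (third-degree and closer) or any child's inbreeding F
exceeds 0.1; both criteria are reported separately.

The X chromosome is excluded from both estimators (they assume
diploidy).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np

from .config import Thresholds, DEFAULT_CONFIG
from .io_formats import Pedigree, VariantRecord, is_chrx

log = logging.getLogger(__name__)


@dataclass(slots=True)
class KinshipEstimate:
    sample_i: str
    sample_j: str
    phi: float
    n_sites_used: int
    related: bool
    usable: bool = True


@dataclass(slots=True)
class InbreedingEstimate:
    sample_id: str
    f: float
    o_hom: int
    e_hom: float
    n_sites: int
    inbred: bool


# ---------------------------------------------------------------------------
# genotype matrix assembly
# ---------------------------------------------------------------------------

def genotype_matrix(records: Sequence[VariantRecord],
                    autosomes_only: bool = True
                    ) -> Tuple[np.ndarray, List[str]]:
    """Stack per-record allele counts into a (sites x samples) int8
    matrix with -1 for missing genotypes."""
    rows = []
    samples: Optional[Tuple[str, ...]] = None
    for rec in records:
        if autosomes_only and is_chrx(rec.chrom):
            continue
        if rec.chrom.removeprefix("chr").upper() in {"Y", "M", "MT"}:
            continue
        if samples is None:
            samples = rec.genotypes.samples
        elif rec.genotypes.samples != samples:
            raise ValueError("records carry inconsistent sample columns")
        rows.append(rec.genotypes.allele_count)
    if not rows:
        return np.empty((0, 0), dtype=np.int8), []
    return np.vstack(rows), list(samples)


def founder_allele_freqs(geno: np.ndarray, samples: Sequence[str],
                         pedigree: Pedigree) -> np.ndarray:
    """Per-site ALT allele frequency from pedigree founders only.

    Children duplicate parental alleles, so including them would bias
    the frequencies used for the inbreeding expectation.
    """
    founder_ids = {m.sample_id for fam in pedigree.families for m in fam.members
                   if m.father_id is None and m.mother_id is None}
    cols = [i for i, s in enumerate(samples) if s in founder_ids]
    if not cols:
        cols = list(range(len(samples)))
    sub = geno[:, cols].astype(np.float64)
    sub[sub < 0] = np.nan
    with np.errstate(invalid="ignore"):
        freqs = np.nanmean(sub, axis=1) / 2.0
    return freqs


# ---------------------------------------------------------------------------
# estimators
# ---------------------------------------------------------------------------

def king_phi(gi: np.ndarray, gj: np.ndarray) -> Tuple[float, int]:
    """KING-robust phi for two genotype vectors; returns (phi, n_sites)."""
    shared = (gi >= 0) & (gj >= 0)
    a, b = gi[shared], gj[shared]
    het_i = a == 1
    het_j = b == 1
    n_hh = int(np.count_nonzero(het_i & het_j))
    n_opp = int(np.count_nonzero(((a == 0) & (b == 2)) | ((a == 2) & (b == 0))))
    n_het_i = int(np.count_nonzero(het_i))
    n_het_j = int(np.count_nonzero(het_j))
    m = min(n_het_i, n_het_j)
    if m == 0:
        return float("nan"), int(shared.sum())
    phi = (n_hh - 2.0 * n_opp) / (2.0 * m) + 0.5 - (n_het_i + n_het_j) / (4.0 * m)
    return phi, int(shared.sum())


def king_kinship(geno: np.ndarray, samples: Sequence[str],
                 pair: Tuple[str, str],
                 thresholds: Optional[Thresholds] = None) -> KinshipEstimate:
    """KING-robust kinship for one sample pair.

    The estimate is flagged unusable (and excluded from family
    classification) when fewer than ``kinship_min_sites`` sites are
    non-missing in both samples.
    """
    th = thresholds or DEFAULT_CONFIG.thresholds
    idx = {s: i for i, s in enumerate(samples)}
    gi = geno[:, idx[pair[0]]]
    gj = geno[:, idx[pair[1]]]
    phi, n_used = king_phi(gi, gj)
    usable = n_used >= th.kinship_min_sites and np.isfinite(phi)
    related = bool(usable and phi >= th.kinship_min)
    return KinshipEstimate(sample_i=pair[0], sample_j=pair[1], phi=phi,
                           n_sites_used=n_used, related=related, usable=usable)


def inbreeding_coefficient(geno: np.ndarray, samples: Sequence[str],
                           sample_id: str, allele_freqs: np.ndarray,
                           thresholds: Optional[Thresholds] = None
                           ) -> InbreedingEstimate:
    """Method-of-moments inbreeding coefficient for one sample.

    Monomorphic sites (frequency 0 or 1) and missing genotypes are
    excluded; raises ``ValueError`` when nothing polymorphic remains.
    """
    th = thresholds or DEFAULT_CONFIG.thresholds
    idx = {s: i for i, s in enumerate(samples)}
    g = geno[:, idx[sample_id]].astype(np.float64)
    p = np.asarray(allele_freqs, dtype=np.float64)
    keep = (g >= 0) & np.isfinite(p) & (p > 0.0) & (p < 1.0)
    if not np.any(keep):
        raise ValueError(f"all sites monomorphic or missing for {sample_id}; "
                         "inbreeding coefficient undefined")
    g, p = g[keep], p[keep]
    n = g.size
    o_hom = int(np.count_nonzero(g != 1))
    e_hom = float(np.sum(1.0 - 2.0 * p * (1.0 - p)))
    denom = n - e_hom
    f = (o_hom - e_hom) / denom if denom != 0 else float("nan")
    return InbreedingEstimate(sample_id=sample_id, f=f, o_hom=o_hom,
                              e_hom=e_hom, n_sites=n,
                              inbred=bool(np.isfinite(f) and f > th.inbreeding_min))


# ---------------------------------------------------------------------------
# family classification
# ---------------------------------------------------------------------------

def classify_consanguinity(pedigree: Pedigree,
                           kinships: Iterable[KinshipEstimate],
                           inbreedings: Iterable[InbreedingEstimate],
                           ) -> Dict[str, Dict[str, object]]:
    """Set the ``consanguineous`` flag on each family.

    A family is consanguineous iff its parental-pair kinship is >= the
    cutoff (inclusive) OR any child's inbreeding F exceeds its cutoff.
    Single-parent families skip the kinship criterion.  Returns a
    per-family log of which criterion fired.
    """
    kin_by_pair: Dict[frozenset, KinshipEstimate] = {
        frozenset((k.sample_i, k.sample_j)): k for k in kinships if k.usable}
    f_by_sample: Dict[str, InbreedingEstimate] = {e.sample_id: e for e in inbreedings}
    report: Dict[str, Dict[str, object]] = {}
    for fam in pedigree.families:
        kin_hit = False
        kin_values = []
        for father, mother in fam.parental_pairs():
            est = kin_by_pair.get(frozenset((father, mother)))
            if est is not None:
                kin_values.append(est.phi)
                kin_hit = kin_hit or est.related
        f_hit = False
        f_values = []
        for child in fam.children():
            est = f_by_sample.get(child.sample_id)
            if est is not None:
                f_values.append(est.f)
                f_hit = f_hit or est.inbred
        fam.consanguineous = bool(kin_hit or f_hit)
        report[fam.family_id] = {
            "consanguineous": fam.consanguineous,
            "kinship_criterion": kin_hit,
            "parental_phi": kin_values,
            "inbreeding_criterion": f_hit,
            "child_f": f_values,
        }
    return report


def estimate_relatedness(records: Sequence[VariantRecord], pedigree: Pedigree,
                         thresholds: Optional[Thresholds] = None
                         ) -> Tuple[List[KinshipEstimate], List[InbreedingEstimate],
                                    Dict[str, Dict[str, object]]]:
    """Convenience driver: parental-pair kinships, per-child inbreeding,
    and consanguinity flags from a record list."""
    th = thresholds or DEFAULT_CONFIG.thresholds
    geno, samples = genotype_matrix(records, autosomes_only=True)
    freqs = founder_allele_freqs(geno, samples, pedigree)
    sample_set = set(samples)
    kinships = []
    inbreedings = []
    for fam in pedigree.families:
        for father, mother in fam.parental_pairs():
            if father in sample_set and mother in sample_set:
                kinships.append(king_kinship(geno, samples, (father, mother), th))
        for child in fam.children():
            if child.sample_id in sample_set:
                inbreedings.append(inbreeding_coefficient(
                    geno, samples, child.sample_id, freqs, th))
    report = classify_consanguinity(pedigree, kinships, inbreedings)
    return kinships, inbreedings, report


def kinship_table(kinships: Sequence[KinshipEstimate]):
    import pandas as pd
    return pd.DataFrame([{
        "sample_i": k.sample_i, "sample_j": k.sample_j, "phi": k.phi,
        "n_sites": k.n_sites_used, "related": k.related, "usable": k.usable,
    } for k in kinships])


def inbreeding_table(inbreedings: Sequence[InbreedingEstimate]):
    import pandas as pd
    return pd.DataFrame([{
        "sample_id": e.sample_id, "f": e.f, "o_hom": e.o_hom,
        "e_hom": e.e_hom, "n_sites": e.n_sites, "inbred": e.inbred,
    } for e in inbreedings])
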