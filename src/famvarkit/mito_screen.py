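"""Mitochondrial heteroplasmy screening against known pathogenic lists.

Input is a per-sample allele-depth table over the mitochondrial
reference (calling itself is upstream).  Heteroplasmy is the alternate
allele depth fraction ad_alt / (ad_ref + ad_alt).  A hit is an
observation matching a known pathogenic variant (position, ref, alt)
with heteroplasmy strictly above the screening threshold (default 2%).
For probands with a sequenced mother, hits are flagged de novo when the
maternal heteroplasmy is undetectable — at or below the threshold, or
no alternate reads at all — a noise-floor definition rather than a
strict zero.

The packaged default known list carries only the three classic
pathogenic variants used in the screen (m.3243A>G / MELAS on the
ASD-associated list; m.11778G>A and m.14484T>C / LHON on the
homoplasmic-disorder list); real screens should supply the full
15-variant and 6-variant lists as a TSV.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence

from .io_formats import Pedigree

LIST_TYPES = ("asd_associated", "homoplasmic_disorder")


@dataclass(slots=True)
class MtObservation:
    sample_id: str
    position: int
    ref: str
    alt: str
    ad_ref: int
    ad_alt: int

    @property
    def total_depth(self) -> int:
        return self.ad_ref + self.ad_alt

    @property
    def heteroplasmy(self) -> Optional[float]:
        """Alt-fraction; None when there is no coverage at the site."""
        total = self.total_depth
        return None if total == 0 else self.ad_alt / total


@dataclass(frozen=True, slots=True)
class MtKnownVariant:
    position: int
    ref: str
    alt: str
    disorder: str
    list_type: str

    def __post_init__(self):
        if self.list_type not in LIST_TYPES:
            raise ValueError(f"unknown list type {self.list_type!r}")


@dataclass(slots=True)
class MtHit:
    observation: MtObservation
    known: MtKnownVariant
    heteroplasmy: float
    is_proband: bool
    de_novo_heteroplasmy: Optional[bool]   # None when no maternal data
    maternal_heteroplasmy: Optional[float]
    unevaluable: bool = False


DEFAULT_KNOWN_VARIANTS = (
    MtKnownVariant(3243, "A", "G", "MELAS", "asd_associated"),
    MtKnownVariant(11778, "G", "A", "LHON", "homoplasmic_disorder"),
    MtKnownVariant(14484, "T", "C", "LHON", "homoplasmic_disorder"),
)


def screen_mtdna(observations: Sequence[MtObservation],
                 known: Sequence[MtKnownVariant] = DEFAULT_KNOWN_VARIANTS,
                 threshold: float = 0.02,
                 pedigree: Optional[Pedigree] = None) -> List[MtHit]:
    """Screen allele-depth observations against the known variant lists.

    Returns one hit per (sample, known variant) with heteroplasmy >
    ``threshold``; sites with zero total depth at a screened position
    are reported as unevaluable hits (heteroplasmy NaN).  When a
    pedigree is given, proband hits carry the maternal comparison.
    """
    known_index: Dict[tuple, MtKnownVariant] = {
        (k.position, k.ref, k.alt): k for k in known}
    by_sample_site: Dict[tuple, MtObservation] = {
        (o.sample_id, o.position, o.ref, o.alt): o for o in observations}

    mother_of: Dict[str, Optional[str]] = {}
    proband_ids = set()
    if pedigree is not None:
        for fam in pedigree.families:
            for m in fam.members:
                mother_of[m.sample_id] = m.mother_id
                if m.affected and (m.father_id or m.mother_id):
                    proband_ids.add(m.sample_id)

    hits: List[MtHit] = []
    for obs in observations:
        kv = known_index.get((obs.position, obs.ref, obs.alt))
        if kv is None:
            continue
        het = obs.heteroplasmy
        if het is None:
            hits.append(MtHit(observation=obs, known=kv,
                              heteroplasmy=float("nan"),
                              is_proband=obs.sample_id in proband_ids,
                              de_novo_heteroplasmy=None,
                              maternal_heteroplasmy=None, unevaluable=True))
            continue
        if het <= threshold:
            continue
        maternal_het: Optional[float] = None
        de_novo: Optional[bool] = None
        mother = mother_of.get(obs.sample_id)
        if mother is not None:
            mobs = by_sample_site.get((mother, obs.position, obs.ref, obs.alt))
            if mobs is None:
                # sparse table: no maternal row means no ALT reads detected
                maternal_het = 0.0
                de_novo = True
            elif mobs.total_depth > 0:
                maternal_het = mobs.heteroplasmy
                de_novo = maternal_het <= threshold
            else:
                de_novo = None  # maternal site uncovered: cannot evaluate
        hits.append(MtHit(observation=obs, known=kv, heteroplasmy=het,
                          is_proband=obs.sample_id in proband_ids,
                          de_novo_heteroplasmy=de_novo,
                          maternal_heteroplasmy=maternal_het))
    return hits


def read_mt_observations(path) -> List[MtObservation]:
    """TSV: sample, position, ref, alt, ad_ref, ad_alt."""
    out = []
    with open(path) as fh:
        fh.readline()
        for line in fh:
            line = line.strip()
            if not line:
                continue
            sample, pos, ref, alt, ad_ref, ad_alt = line.split("\t")[:6]
            out.append(MtObservation(sample_id=sample, position=int(pos),
                                     ref=ref, alt=alt, ad_ref=int(ad_ref),
                                     ad_alt=int(ad_alt)))
    return out


def write_mt_observations(observations: Sequence[MtObservation], path) -> None:
    with open(path, "w") as fh:
        fh.write("sample\tposition\tref\talt\tad_ref\tad_alt\n")
        for o in observations:
            fh.write(f"{o.sample_id}\t{o.position}\t{o.ref}\t{o.alt}\t"
                     f"{o.ad_ref}\t{o.ad_alt}\n")


def read_mt_known(path) -> List[MtKnownVariant]:
    """TSV: position, ref, alt, disorder, list_type."""
    out = []
    with open(path) as fh:
        fh.readline()
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            pos, ref, alt, disorder, list_type = line.split("\t")[:5]
            out.append(MtKnownVariant(position=int(pos), ref=ref, alt=alt,
                                      disorder=disorder, list_type=list_type))
    return out
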