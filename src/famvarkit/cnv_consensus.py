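"""Multi-caller CNV consensus, family-aware inheritance, and overlap
against known ASD/NDD genes, regions, and tandem-repeat-expansion genes.

Consensus merging follows a two-stage scheme: calls of the same type
whose start coordinates differ by at most the merge window (default
500 bp) AND whose end coordinates differ by at most the window are
merged transitively (single linkage), first within each sample and then
across samples.  Per-sample clusters supported by fewer than two
distinct callers are discarded.  Representative coordinates of a
cluster are the per-endpoint medians of its members.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, FrozenSet, Iterable, List, Mapping, Optional, Sequence, Set, Tuple

import numpy as np
from intervaltree import IntervalTree

from .config import Thresholds, DEFAULT_CONFIG
from .io_formats import Family


@dataclass(slots=True)
class CnvCall:
    """One caller's deletion/duplication call (1-based inclusive)."""

    sample_id: str
    chrom: str
    start: int
    end: int
    type: str          # "DEL" | "DUP"
    caller: str

    def __post_init__(self):
        if self.end < self.start:
            raise ValueError(f"end < start for {self.chrom}:{self.start}-{self.end}")
        if self.type not in {"DEL", "DUP"}:
            raise ValueError(f"unknown CNV type {self.type!r}")

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass(slots=True)
class ConsensusCnv:
    """A merged CNV supported by >= 2 callers in at least one carrier."""

    chrom: str
    start: int
    end: int
    type: str
    sample_ids: Set[str] = field(default_factory=set)
    callers: Set[str] = field(default_factory=set)
    af: Optional[float] = None
    inheritance: Optional[str] = None    # de_novo | homozygous | inherited
    known_label: Optional[str] = None    # "known" | "novel"
    overlapped: List[str] = field(default_factory=list)

    @property
    def key(self) -> str:
        return f"{self.chrom}:{self.start}-{self.end}:{self.type}"


@dataclass(slots=True)
class TreLocus:
    """A tandem-repeat expansion locus with its carrier samples."""

    chrom: str
    start: int
    end: int
    motif: str
    carriers: Set[str] = field(default_factory=set)


# ---------------------------------------------------------------------------
# merging
# ---------------------------------------------------------------------------

def _within_window(a: Tuple[int, int], b: Tuple[int, int], window: int) -> bool:
    return abs(a[0] - b[0]) <= window and abs(a[1] - b[1]) <= window


def _single_linkage_clusters(intervals: Sequence[Tuple[int, int]],
                             window: int) -> List[List[int]]:
    """Transitive closure of the pairwise within-window relation.

    Intervals are sorted by start; since linkage requires start
    coordinates within ``window``, it suffices to test each interval
    against the sorted neighbours whose starts are within the window,
    which keeps the scan near-linear for sparse data.
    """
    n = len(intervals)
    parent = list(range(n))

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(x, y):
        rx, ry = find(x), find(y)
        if rx != ry:
            parent[ry] = rx

    order = sorted(range(n), key=lambda i: intervals[i])
    for a in range(n):
        i = order[a]
        for b in range(a + 1, n):
            j = order[b]
            if intervals[j][0] - intervals[i][0] > window:
                break
            if _within_window(intervals[i], intervals[j], window):
                union(i, j)
    clusters: Dict[int, List[int]] = {}
    for i in range(n):
        clusters.setdefault(find(i), []).append(i)
    return list(clusters.values())


def consensus_and_merge(callsets: Mapping[str, Sequence[CnvCall]],
                        window: int = 500,
                        min_callers: int = 2) -> List[ConsensusCnv]:
    """Two-stage consensus merge of per-caller CNV call sets.

    ``callsets`` maps caller name -> calls (the caller attribute on each
    call must agree with its key).  Stage 1 merges within each sample
    and keeps clusters seen by >= ``min_callers`` distinct callers;
    stage 2 merges the surviving per-sample consensus intervals across
    samples under the same same-type/500 bp rule.  Output is sorted by
    (chrom, start).
    """
    if window < 0:
        raise ValueError("merge window must be >= 0")
    calls: List[CnvCall] = []
    for caller, cs in callsets.items():
        for c in cs:
            if c.caller != caller:
                raise ValueError(f"call from {c.caller!r} listed under {caller!r}")
            calls.append(c)

    # stage 1: per (sample, chrom, type)
    stage1: List[ConsensusCnv] = []
    groups: Dict[Tuple[str, str, str], List[CnvCall]] = {}
    for c in calls:
        groups.setdefault((c.sample_id, c.chrom, c.type), []).append(c)
    for (sample, chrom, cnv_type), group in groups.items():
        intervals = [(c.start, c.end) for c in group]
        for idxs in _single_linkage_clusters(intervals, window):
            members = [group[i] for i in idxs]
            callers = {m.caller for m in members}
            if len(callers) < min_callers:
                continue
            stage1.append(ConsensusCnv(
                chrom=chrom,
                start=int(np.median([m.start for m in members])),
                end=int(np.median([m.end for m in members])),
                type=cnv_type,
                sample_ids={sample},
                callers=callers,
            ))

    # stage 2: population-level, per (chrom, type)
    merged: List[ConsensusCnv] = []
    groups2: Dict[Tuple[str, str], List[ConsensusCnv]] = {}
    for c in stage1:
        groups2.setdefault((c.chrom, c.type), []).append(c)
    for (chrom, cnv_type), group in groups2.items():
        intervals = [(c.start, c.end) for c in group]
        for idxs in _single_linkage_clusters(intervals, window):
            members = [group[i] for i in idxs]
            merged.append(ConsensusCnv(
                chrom=chrom,
                start=int(np.median([m.start for m in members])),
                end=int(np.median([m.end for m in members])),
                type=cnv_type,
                sample_ids=set().union(*(m.sample_ids for m in members)),
                callers=set().union(*(m.callers for m in members)),
            ))
    merged.sort(key=lambda c: (c.chrom, c.start, c.end, c.type))
    return merged


# ---------------------------------------------------------------------------
# allele frequencies from reference SV sets
# ---------------------------------------------------------------------------

def reciprocal_overlap(a: Tuple[int, int], b: Tuple[int, int]) -> float:
    inter = min(a[1], b[1]) - max(a[0], b[0]) + 1
    if inter <= 0:
        return 0.0
    return min(inter / (a[1] - a[0] + 1), inter / (b[1] - b[0] + 1))


def match_reference_af(cnv: ConsensusCnv,
                       reference: Sequence[Tuple[str, int, int, str, float]],
                       min_reciprocal: float = 0.5) -> Optional[float]:
    """Best-matching AF from a reference SV set ((chrom, start, end,
    type, af) tuples, 1-based inclusive) at >= 50% reciprocal overlap
    and same type; None when nothing matches."""
    best = None
    for chrom, start, end, cnv_type, af in reference:
        if chrom != cnv.chrom or cnv_type != cnv.type:
            continue
        ro = reciprocal_overlap((cnv.start, cnv.end), (start, end))
        if ro >= min_reciprocal and (best is None or af > best):
            best = af
    return best


# ---------------------------------------------------------------------------
# inheritance
# ---------------------------------------------------------------------------

def cnv_inheritance(consensus: Sequence[ConsensusCnv], family: Family,
                    af_reference: Sequence[Tuple[str, int, int, str, float]] = (),
                    thresholds: Optional[Thresholds] = None) -> List[ConsensusCnv]:
    """Annotate consensus CNVs with their inheritance in one family.

    de novo: proband carries, neither parent carries, reference AF <
    0.1% (missing AF counts as absent, i.e. 0); requires a complete
    trio.  homozygous: proband and both parents carry a deletion
    (proband presumed copy-number 0 from the biparental support
    pattern), AF < 1%.  inherited: proband plus >= 1 parent carry.
    Returns the annotated subset relevant to this family.
    """
    th = thresholds or DEFAULT_CONFIG.thresholds
    out = []
    for cnv in consensus:
        af = cnv.af
        if af is None:
            af = match_reference_af(cnv, af_reference, th.cnv_reciprocal_overlap)
        af_value = 0.0 if af is None else af
        for proband in family.probands():
            if proband.sample_id not in cnv.sample_ids:
                continue
            father, mother = family.parents_of(proband)
            father_carries = father is not None and father.sample_id in cnv.sample_ids
            mother_carries = mother is not None and mother.sample_id in cnv.sample_ids
            complete = father is not None and mother is not None
            inheritance = None
            if complete and not father_carries and not mother_carries:
                if af_value < th.cnv_denovo_af_max:
                    inheritance = "de_novo"
            elif (cnv.type == "DEL" and father_carries and mother_carries
                  and af_value < th.cnv_hom_af_max):
                inheritance = "homozygous"
            elif father_carries or mother_carries:
                inheritance = "inherited"
            if inheritance is not None:
                annotated = ConsensusCnv(
                    chrom=cnv.chrom, start=cnv.start, end=cnv.end,
                    type=cnv.type, sample_ids=set(cnv.sample_ids),
                    callers=set(cnv.callers), af=af,
                    inheritance=inheritance,
                    known_label=cnv.known_label,
                    overlapped=list(cnv.overlapped))
                out.append(annotated)
                break
    return out


# ---------------------------------------------------------------------------
# known-gene / known-region overlap
# ---------------------------------------------------------------------------

def _build_trees(intervals: Iterable[Tuple[str, int, int, str]]
                 ) -> Dict[str, IntervalTree]:
    trees: Dict[str, IntervalTree] = {}
    for chrom, start, end, name in intervals:
        if end < start:
            warnings.warn(f"empty interval {name} skipped")
            continue
        # half-open internally for the tree; inputs are 1-based inclusive
        trees.setdefault(chrom, IntervalTree()).addi(start, end + 1, name)
    return trees


def overlap_known(cnvs: Sequence[ConsensusCnv],
                  known_intervals: Iterable[Tuple[str, int, int, str]]
                  ) -> List[ConsensusCnv]:
    """Label each CNV "known" on any base-pair overlap with a known
    ASD/NDD gene or region interval (1-based inclusive), else "novel";
    the overlapped names are attached."""
    trees = _build_trees(known_intervals)
    for cnv in cnvs:
        tree = trees.get(cnv.chrom)
        hits = sorted({iv.data for iv in tree.overlap(cnv.start, cnv.end + 1)}) \
            if tree is not None else []
        cnv.known_label = "known" if hits else "novel"
        cnv.overlapped = hits
    return list(cnvs)


def tre_overlap(tres: Sequence[TreLocus],
                tre_gene_intervals: Iterable[Tuple[str, int, int, str]]
                ) -> List[Tuple[TreLocus, List[str]]]:
    """Match TRE loci against the known TRE-associated ASD gene list.

    Returns (locus, matched gene symbols) for loci overlapping at least
    one gene interval.  The number of indexed genes is recorded on the
    returned function attribute ``tre_overlap.last_n_genes`` for
    logging.
    """
    intervals = list(tre_gene_intervals)
    trees = _build_trees(intervals)
    tre_overlap.last_n_genes = len({name for _, _, _, name in intervals})
    matches = []
    for locus in tres:
        tree = trees.get(locus.chrom)
        if tree is None:
            continue
        hits = sorted({iv.data for iv in tree.overlap(locus.start, locus.end + 1)})
        if hits:
            matches.append((locus, hits))
    return matches


def read_region_intervals(path) -> List[Tuple[str, int, int, str]]:
    """BED (0-based half-open, name in column 4) -> 1-based inclusive
    (chrom, start, end, name) tuples."""
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            chrom, start, end = parts[0], int(parts[1]), int(parts[2])
            name = parts[3] if len(parts) > 3 else f"{chrom}:{start}-{end}"
            out.append((chrom, start + 1, end, name))
    return out


def read_tre_table(path) -> List[TreLocus]:
    """TSV of TRE loci: chrom, start, end (0-based half-open), motif,
    sample; one row per carrier."""
    loci: Dict[Tuple[str, int, int, str], TreLocus] = {}
    with open(path) as fh:
        header = fh.readline()
        for line in fh:
            line = line.strip()
            if not line:
                continue
            chrom, start, end, motif, sample = line.split("\t")[:5]
            key = (chrom, int(start) + 1, int(end), motif)
            locus = loci.setdefault(key, TreLocus(
                chrom=chrom, start=int(start) + 1, end=int(end), motif=motif))
            locus.carriers.add(sample)
    return list(loci.values())


def write_tre_table(loci: Sequence[TreLocus], path) -> None:
    with open(path, "w") as fh:
        fh.write("chrom\tstart\tend\tmotif\tsample\n")
        for locus in loci:
            for sample in sorted(locus.carriers):
                fh.write(f"{locus.chrom}\t{locus.start - 1}\t{locus.end}\t"
                         f"{locus.motif}\t{sample}\n")
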