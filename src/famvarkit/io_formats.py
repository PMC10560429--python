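"""Readers and writers for the file formats the pipeline touches.

VCF 4.x (via cyvcf2), 6-column PED pedigrees, BED interval masks,
BED-like CNV call tables, and the TSV side tables (gene panel with mode
of inheritance, gene constraint scores, cross-cohort recurrence counts).
Everything is normalized into the package's domain types on read:

* all internal positions are 1-based (VCF convention); BED inputs are
  0-based half-open and converted on read;
* multiallelic VCF records are split into one biallelic record per ALT
  before anything downstream sees them;
* missing annotations stay missing (``None``) rather than being
  zero-filled — except population allele frequencies, which the rarity
  filter treats as 0 (absent from that database).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from cyvcf2 import VCF
from intervaltree import IntervalTree

from .config import FieldMap, DEFAULT_CONFIG

log = logging.getLogger(__name__)

MISSING_INT32 = np.iinfo(np.int32).min


class FormatError(ValueError):
    """Raised for malformed input files."""


# ---------------------------------------------------------------------------
# consequence / predictor vocabularies
# ---------------------------------------------------------------------------

LOF_CONSEQUENCES = frozenset({
    "stop_gained", "frameshift_insertion", "frameshift_deletion",
    "splice_acceptor", "splice_donor",
})
CONSEQUENCES = tuple(sorted(LOF_CONSEQUENCES)) + ("missense", "other")

_CATEGORICAL_PREDICTOR_VALUES = {
    "sift": {"deleterious", "tolerated"},
    "pph2_hdiv": {"probably_damaging", "possibly_damaging", "benign"},
    "pph2_hvar": {"probably_damaging", "possibly_damaging", "benign"},
    "lrt": {"deleterious", "neutral"},
    "mutation_assessor": {"high", "medium", "low", "neutral"},
    "mutation_taster": {"deleterious", "polymorphism"},
    "provean": {"deleterious", "neutral"},
}


@dataclass(frozen=True, slots=True)
class PredictorProfile:
    """The nine in-silico predictor slots; any slot may be missing."""

    cadd_phred: Optional[float] = None
    sift: Optional[str] = None
    pph2_hdiv: Optional[str] = None
    pph2_hvar: Optional[str] = None
    lrt: Optional[str] = None
    mutation_assessor: Optional[str] = None
    mutation_taster: Optional[str] = None
    mpc: Optional[float] = None
    provean: Optional[str] = None

    def __post_init__(self):
        for name, allowed in _CATEGORICAL_PREDICTOR_VALUES.items():
            value = getattr(self, name)
            if value is not None and value not in allowed:
                raise ValueError(f"invalid {name} call {value!r}")


EMPTY_PREDICTORS = PredictorProfile()


# ---------------------------------------------------------------------------
# genotype containers
# ---------------------------------------------------------------------------

@dataclass(slots=True)
class GenotypeCall:
    """One sample's genotype at one biallelic site.

    ``allele_count`` is the number of ALT alleles (0/1/2, with 1 also
    encoding a hemizygous ALT male on chrX) or ``None`` when the genotype
    is missing.  Missing genotypes are excluded from all filters.
    """

    sample_id: str
    allele_count: Optional[int]
    gq: Optional[int] = None
    dp: Optional[int] = None
    ad_ref: Optional[int] = None
    ad_alt: Optional[int] = None


class GenotypeTable:
    """Column-oriented storage of per-sample genotype calls.

    Backed by numpy arrays so that cohort-scale VCFs (tens of thousands
    of sites times hundreds of samples) stay cheap; negative sentinel
    values encode missing.
    """

    __slots__ = ("samples", "allele_count", "gq", "dp", "ad_ref", "ad_alt")

    # sample-name -> column maps, shared across the many records of one
    # cohort (building one dict per record would dominate memory)
    _index_cache: Dict[Tuple[str, ...], Dict[str, int]] = {}

    def __init__(self, samples: Sequence[str], allele_count, gq, dp, ad_ref, ad_alt):
        self.samples = samples if isinstance(samples, tuple) else tuple(samples)
        self.allele_count = np.asarray(allele_count, dtype=np.int8)
        self.gq = np.asarray(gq, dtype=np.int32)
        self.dp = np.asarray(dp, dtype=np.int32)
        self.ad_ref = np.asarray(ad_ref, dtype=np.int32)
        self.ad_alt = np.asarray(ad_alt, dtype=np.int32)

    # -- construction ------------------------------------------------------
    @classmethod
    def from_calls(cls, calls: Iterable[GenotypeCall]) -> "GenotypeTable":
        calls = list(calls)
        def enc(v, sentinel):
            return sentinel if v is None else v
        return cls(
            [c.sample_id for c in calls],
            [enc(c.allele_count, -1) for c in calls],
            [enc(c.gq, MISSING_INT32) for c in calls],
            [enc(c.dp, MISSING_INT32) for c in calls],
            [enc(c.ad_ref, MISSING_INT32) for c in calls],
            [enc(c.ad_alt, MISSING_INT32) for c in calls],
        )

    # -- access ------------------------------------------------------------
    def __len__(self) -> int:
        return len(self.samples)

    def _index(self) -> Dict[str, int]:
        idx = GenotypeTable._index_cache.get(self.samples)
        if idx is None:
            idx = {s: i for i, s in enumerate(self.samples)}
            GenotypeTable._index_cache[self.samples] = idx
        return idx

    def __contains__(self, sample_id: str) -> bool:
        return sample_id in self._index()

    def index(self, sample_id: str) -> int:
        return self._index()[sample_id]

    def call(self, sample_id: str) -> GenotypeCall:
        i = self._index()[sample_id]
        def dec(arr, sentinel):
            v = int(arr[i])
            return None if v == sentinel else v
        return GenotypeCall(
            sample_id=sample_id,
            allele_count=dec(self.allele_count, -1),
            gq=dec(self.gq, MISSING_INT32),
            dp=dec(self.dp, MISSING_INT32),
            ad_ref=dec(self.ad_ref, MISSING_INT32),
            ad_alt=dec(self.ad_alt, MISSING_INT32),
        )

    def calls(self) -> List[GenotypeCall]:
        return [self.call(s) for s in self.samples]

    def allele_count_of(self, sample_id: str) -> Optional[int]:
        v = int(self.allele_count[self._index()[sample_id]])
        return None if v == -1 else v


@dataclass(slots=True)
class VariantRecord:
    """One biallelic annotated site with per-sample genotypes."""

    chrom: str
    pos: int
    ref: str
    alt: str
    filter_status: str = "PASS"
    consequence: str = "other"
    gene: Optional[str] = None
    pop_afs: Dict[str, Optional[float]] = field(default_factory=dict)
    predictors: PredictorProfile = EMPTY_PREDICTORS
    acmg_label: Optional[str] = None
    genotypes: Optional[GenotypeTable] = None
    in_lcr: bool = False
    # per-sample QC verdict, aligned with genotypes.samples; filled by qc_filter
    qc_pass: Optional[np.ndarray] = None

    def __post_init__(self):
        if self.pos < 1:
            raise ValueError(f"position must be >= 1, got {self.pos}")

    @property
    def key(self) -> str:
        return f"{self.chrom}:{self.pos}:{self.ref}:{self.alt}"

    def max_pop_af(self) -> float:
        """Largest known population AF; missing entries count as 0."""
        vals = [v for v in self.pop_afs.values() if v is not None]
        return max(vals) if vals else 0.0


# ---------------------------------------------------------------------------
# pedigree
# ---------------------------------------------------------------------------

@dataclass(slots=True)
class Member:
    sample_id: str
    sex: str                      # "male" | "female" | "unknown"
    affected: Optional[bool]      # None = missing phenotype
    father_id: Optional[str] = None
    mother_id: Optional[str] = None


@dataclass(slots=True)
class Family:
    family_id: str
    members: List[Member] = field(default_factory=list)
    consanguineous: Optional[bool] = None

    def member(self, sample_id: str) -> Member:
        for m in self.members:
            if m.sample_id == sample_id:
                return m
        raise KeyError(sample_id)

    def ids(self) -> List[str]:
        return [m.sample_id for m in self.members]

    def probands(self) -> List[Member]:
        """Affected members that have at least one parent link."""
        return [m for m in self.members
                if m.affected and (m.father_id or m.mother_id)]

    def children(self) -> List[Member]:
        return [m for m in self.members if m.father_id or m.mother_id]

    def parents_of(self, m: Member) -> Tuple[Optional[Member], Optional[Member]]:
        ids = set(self.ids())
        father = self.member(m.father_id) if m.father_id in ids else None
        mother = self.member(m.mother_id) if m.mother_id in ids else None
        return father, mother

    def is_complete_trio(self, proband: Member) -> bool:
        father, mother = self.parents_of(proband)
        return father is not None and mother is not None

    def parental_pairs(self) -> List[Tuple[str, str]]:
        pairs = {(m.father_id, m.mother_id) for m in self.members
                 if m.father_id and m.mother_id}
        ids = set(self.ids())
        return sorted((f, mo) for f, mo in pairs if f in ids and mo in ids)


@dataclass(slots=True)
class Pedigree:
    families: List[Family] = field(default_factory=list)

    def family(self, family_id: str) -> Family:
        for fam in self.families:
            if fam.family_id == family_id:
                return fam
        raise KeyError(family_id)

    def sample_ids(self) -> List[str]:
        return [m.sample_id for fam in self.families for m in fam.members]

    def complete_trio_families(self) -> List[Family]:
        return [fam for fam in self.families
                if any(fam.is_complete_trio(p) for p in fam.probands())]


# ---------------------------------------------------------------------------
# side tables
# ---------------------------------------------------------------------------

@dataclass(frozen=True, slots=True)
class PanelEntry:
    gene: str
    moi: str  # "dominant" | "biallelic" | "x_linked"


@dataclass(frozen=True, slots=True)
class ConstraintScores:
    gene: str
    pli: Optional[float] = None
    prec: Optional[float] = None


_MOI_SYNONYMS = {
    "dominant": "dominant", "ad": "dominant",
    "biallelic": "biallelic", "ar": "biallelic", "recessive": "biallelic",
    "x_linked": "x_linked", "xl": "x_linked", "x-linked": "x_linked",
}


# ---------------------------------------------------------------------------
# BED masks
# ---------------------------------------------------------------------------

def read_bed(path) -> Dict[str, IntervalTree]:
    """Read a BED file (0-based half-open) into per-chromosome trees.

    Tree coordinates stay 0-based half-open; use :func:`position_in_mask`
    to query with 1-based positions.
    """
    trees: Dict[str, IntervalTree] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise FormatError(f"{path}: line {lineno}: expected >= 3 BED columns")
            chrom, start, end = parts[0], int(parts[1]), int(parts[2])
            if end <= start:
                warnings.warn(f"{path}: line {lineno}: empty interval skipped")
                continue
            trees.setdefault(chrom, IntervalTree()).addi(start, end)
    return trees


def position_in_mask(trees: Mapping[str, IntervalTree], chrom: str, pos: int) -> bool:
    """Is the 1-based position ``pos`` inside any mask interval?"""
    tree = trees.get(chrom)
    return bool(tree is not None and tree.overlaps_point(pos - 1))


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

def _info_str(variant, key: str) -> Optional[str]:
    value = variant.INFO.get(key)
    if value is None:
        return None
    if isinstance(value, bytes):
        value = value.decode()
    value = str(value)
    return value if value not in (".", "") else None


def _info_float(variant, key: str) -> Optional[float]:
    value = variant.INFO.get(key)
    if value is None:
        return None
    try:
        return float(value)
    except (TypeError, ValueError):
        return None


def _categorical(variant, key: str, slot: str) -> Optional[str]:
    value = _info_str(variant, key)
    if value is None:
        return None
    value = value.lower()
    if value not in _CATEGORICAL_PREDICTOR_VALUES[slot]:
        warnings.warn(f"unrecognized {slot} value {value!r}; treated as missing")
        return None
    return value


def _predictors_from_info(variant, fm: FieldMap) -> PredictorProfile:
    return PredictorProfile(
        cadd_phred=_info_float(variant, fm.cadd),
        sift=_categorical(variant, fm.sift, "sift"),
        pph2_hdiv=_categorical(variant, fm.pph2_hdiv, "pph2_hdiv"),
        pph2_hvar=_categorical(variant, fm.pph2_hvar, "pph2_hvar"),
        lrt=_categorical(variant, fm.lrt, "lrt"),
        mutation_assessor=_categorical(variant, fm.mutation_assessor, "mutation_assessor"),
        mutation_taster=_categorical(variant, fm.mutation_taster, "mutation_taster"),
        mpc=_info_float(variant, fm.mpc),
        provean=_categorical(variant, fm.provean, "provean"),
    )


def read_vcf(path, lcr_mask: Optional[Mapping[str, IntervalTree]] = None,
             field_map: Optional[FieldMap] = None) -> List[VariantRecord]:
    """Read a VCF into :class:`VariantRecord` objects.

    Multiallelic sites are split into one record per ALT allele, with the
    genotype of each sample re-coded against that ALT (alleles matching
    the ALT count as alternate, everything else as reference) and the AD
    of the split allele taken as (ref depth, that ALT's depth).
    """
    path = str(path)
    fm = field_map or DEFAULT_CONFIG.fields
    with open(path) as fh:
        first = fh.readline()
    if not first.startswith("##fileformat=VCF"):
        raise FormatError(f"{path}: line 1: missing ##fileformat=VCF header")

    if lcr_mask:
        vcf_contigs = set(VCF(path).seqnames)
        unknown = set(lcr_mask) - vcf_contigs
        if vcf_contigs and unknown:
            warnings.warn(
                "mask contigs absent from VCF header ignored: "
                + ", ".join(sorted(unknown)))

    vcf = VCF(path, gts012=False)
    samples = tuple(vcf.samples)
    n = len(samples)
    records: List[VariantRecord] = []
    for variant in vcf:
        alts = variant.ALT
        gt_arr = variant.genotype.array() if n else np.empty((0, 3), dtype=np.int16)
        alleles = gt_arr[:, :-1]  # last column is phasing
        gq = variant.format("GQ")
        dp = variant.format("DP")
        ad = variant.format("AD")
        pop_afs_all = {db: _info_float(variant, key) for db, key in fm.af_keys.items()}
        consequence = (_info_str(variant, fm.consequence) or "other")
        if consequence not in CONSEQUENCES:
            consequence = "other"
        gene = _info_str(variant, fm.gene)
        acmg = _info_str(variant, fm.acmg)
        predictors = _predictors_from_info(variant, fm)
        filt = variant.FILTER or "PASS"

        for k, alt in enumerate(alts, start=1):
            # -1 encodes a missing allele, -2 pads haploid calls
            ac = (alleles == k).sum(axis=1).astype(np.int8)
            missing = (alleles == -1).any(axis=1) | (alleles <= -2).all(axis=1)
            ac[missing] = -1
            def fmt_col(arr, col):
                out = np.full(n, MISSING_INT32, dtype=np.int64)
                if arr is None:
                    return out
                vals = arr[:, col] if arr.ndim == 2 else arr
                vals = np.asarray(vals)
                ok = (vals >= 0) & (vals < 2**31 - 1)
                out[ok] = vals[ok]
                return out
            table = GenotypeTable(
                samples, ac,
                fmt_col(gq, 0), fmt_col(dp, 0),
                fmt_col(ad, 0), fmt_col(ad, k),
            )
            rec = VariantRecord(
                chrom=variant.CHROM, pos=variant.POS,
                ref=variant.REF, alt=str(alt),
                filter_status=filt, consequence=consequence, gene=gene,
                pop_afs=dict(pop_afs_all), predictors=predictors,
                acmg_label=acmg, genotypes=table,
            )
            if lcr_mask is not None:
                rec.in_lcr = position_in_mask(lcr_mask, rec.chrom, rec.pos)
            records.append(rec)
    return records


_VCF_INFO_HEADER = """\
##INFO=<ID={gene},Number=1,Type=String,Description="Gene symbol">
##INFO=<ID={csq},Number=1,Type=String,Description="Consequence">
##INFO=<ID={acmg},Number=1,Type=String,Description="ACMG label (pass-through)">
##INFO=<ID={cadd},Number=1,Type=Float,Description="CADD PHRED score">
##INFO=<ID={sift},Number=1,Type=String,Description="SIFT call">
##INFO=<ID={hdiv},Number=1,Type=String,Description="PolyPhen2 HDIV call">
##INFO=<ID={hvar},Number=1,Type=String,Description="PolyPhen2 HVAR call">
##INFO=<ID={lrt},Number=1,Type=String,Description="LRT call">
##INFO=<ID={ma},Number=1,Type=String,Description="MutationAssessor call">
##INFO=<ID={mt},Number=1,Type=String,Description="MutationTaster call">
##INFO=<ID={mpc},Number=1,Type=Float,Description="MPC score">
##INFO=<ID={provean},Number=1,Type=String,Description="PROVEAN call">
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="Genotype quality">
##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">
##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">
"""


def write_vcf(records: Sequence[VariantRecord], path,
              field_map: Optional[FieldMap] = None,
              contig_lengths: Optional[Mapping[str, int]] = None) -> None:
    """Write biallelic records as a VCF 4.2 file (plain text)."""
    fm = field_map or DEFAULT_CONFIG.fields
    if not records:
        samples: List[str] = []
    else:
        samples = list(records[0].genotypes.samples)
    contigs = dict(contig_lengths or {})
    for rec in records:
        contigs.setdefault(rec.chrom, max(rec.pos + 1_000_000,
                                          contigs.get(rec.chrom, 0)))
    gt_strings = np.array(["0/0", "0/1", "1/1", "./."])
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for chrom, length in contigs.items():
            fh.write(f"##contig=<ID={chrom},length={length}>\n")
        fh.write(_VCF_INFO_HEADER.format(
            gene=fm.gene, csq=fm.consequence, acmg=fm.acmg, cadd=fm.cadd,
            sift=fm.sift, hdiv=fm.pph2_hdiv, hvar=fm.pph2_hvar, lrt=fm.lrt,
            ma=fm.mutation_assessor, mt=fm.mutation_taster, mpc=fm.mpc,
            provean=fm.provean))
        for db, key in fm.af_keys.items():
            fh.write(f'##INFO=<ID={key},Number=1,Type=Float,'
                     f'Description="Allele frequency in {db}">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(samples) + "\n")
        for rec in sorted(records, key=lambda r: (r.chrom, r.pos, r.alt)):
            info = [f"{fm.consequence}={rec.consequence}"]
            if rec.gene:
                info.append(f"{fm.gene}={rec.gene}")
            if rec.acmg_label:
                info.append(f"{fm.acmg}={rec.acmg_label}")
            for db, key in fm.af_keys.items():
                af = rec.pop_afs.get(db)
                if af is not None:
                    info.append(f"{key}={af:.6g}")
            p = rec.predictors
            for key, value in ((fm.cadd, p.cadd_phred), (fm.sift, p.sift),
                               (fm.pph2_hdiv, p.pph2_hdiv), (fm.pph2_hvar, p.pph2_hvar),
                               (fm.lrt, p.lrt), (fm.mutation_assessor, p.mutation_assessor),
                               (fm.mutation_taster, p.mutation_taster),
                               (fm.mpc, p.mpc), (fm.provean, p.provean)):
                if value is not None:
                    info.append(f"{key}={value}")
            table = rec.genotypes
            ac = table.allele_count
            gts = gt_strings[np.where(ac < 0, 3, ac)]
            cols = []
            for j in range(len(samples)):
                gt = gts[j]
                gq = table.gq[j]; dpv = table.dp[j]
                adr = table.ad_ref[j]; ada = table.ad_alt[j]
                cols.append("%s:%s:%s:%s" % (
                    gt,
                    "." if gq == MISSING_INT32 else int(gq),
                    "." if dpv == MISSING_INT32 else int(dpv),
                    "." if adr == MISSING_INT32 or ada == MISSING_INT32
                    else "%d,%d" % (adr, ada)))
            fh.write("%s\t%d\t.\t%s\t%s\t.\t%s\t%s\tGT:GQ:DP:AD\t%s\n" % (
                rec.chrom, rec.pos, rec.ref, rec.alt, rec.filter_status,
                ";".join(info), "\t".join(cols)))


def is_chrx(chrom: str) -> bool:
    return chrom.removeprefix("chr").upper() == "X"


# ---------------------------------------------------------------------------
# PED
# ---------------------------------------------------------------------------

_SEX_CODES = {"1": "male", "2": "female", "0": "unknown"}
_PHENO_CODES = {"2": True, "1": False, "0": None, "-9": None}


def read_ped(path) -> Pedigree:
    """Read a 6-column PED file (family, individual, father, mother, sex,
    phenotype) into a :class:`Pedigree`."""
    families: Dict[str, Family] = {}
    seen = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) < 6:
                raise FormatError(f"{path}: line {lineno}: expected 6 columns")
            fid, iid, father, mother, sex, pheno = parts[:6]
            if (fid, iid) in seen:
                raise FormatError(f"{path}: line {lineno}: duplicate individual "
                                  f"({fid}, {iid})")
            seen.add((fid, iid))
            fam = families.setdefault(fid, Family(family_id=fid))
            fam.members.append(Member(
                sample_id=iid,
                sex=_SEX_CODES.get(sex, "unknown"),
                affected=_PHENO_CODES.get(pheno),
                father_id=None if father == "0" else father,
                mother_id=None if mother == "0" else mother,
            ))
    ped = Pedigree(families=list(families.values()))
    missing = []
    for fam in ped.families:
        ids = set(fam.ids())
        for m in fam.members:
            for pid in (m.father_id, m.mother_id):
                if pid is not None and pid not in ids:
                    missing.append((fam.family_id, m.sample_id, pid))
    if missing:
        detail = "; ".join(f"{f}:{c} -> {p}" for f, c, p in missing)
        raise FormatError(f"{path}: parent ids not present in family: {detail}")
    return ped


def write_ped(pedigree: Pedigree, path) -> None:
    sex_out = {"male": "1", "female": "2", "unknown": "0"}
    pheno_out = {True: "2", False: "1", None: "0"}
    with open(path, "w") as fh:
        for fam in pedigree.families:
            for m in fam.members:
                fh.write("\t".join([
                    fam.family_id, m.sample_id,
                    m.father_id or "0", m.mother_id or "0",
                    sex_out[m.sex], pheno_out[m.affected]]) + "\n")


# ---------------------------------------------------------------------------
# panel / constraints / recurrence
# ---------------------------------------------------------------------------

def read_panel(path) -> List[PanelEntry]:
    """Read the gene panel TSV (columns ``gene``, ``moi``).

    MOI strings are case-insensitive; AD/AR/XL synonyms are accepted.
    Duplicate (gene, moi) rows are removed; counts per MOI are logged.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.empty:
        warnings.warn(f"{path}: panel file has no entries")
        return []
    entries = []
    for idx, row in df.iterrows():
        moi_raw = str(row["moi"]).strip().lower()
        if moi_raw not in _MOI_SYNONYMS:
            raise FormatError(f"{path}: row {idx + 2}: unknown mode of "
                              f"inheritance {row['moi']!r}")
        entries.append(PanelEntry(gene=str(row["gene"]).strip(),
                                  moi=_MOI_SYNONYMS[moi_raw]))
    unique = sorted(set(entries), key=lambda e: (e.moi, e.gene))
    counts = pd.Series([e.moi for e in unique]).value_counts().to_dict()
    log.info("panel loaded: %d genes (%s)", len(unique),
             ", ".join(f"{v} {k}" for k, v in sorted(counts.items())))
    return unique


def write_panel(entries: Sequence[PanelEntry], path) -> None:
    pd.DataFrame([{"gene": e.gene, "moi": e.moi} for e in entries]) \
        .to_csv(path, sep="\t", index=False)


def panel_index(entries: Iterable[PanelEntry]) -> Dict[str, List[str]]:
    """gene symbol -> sorted list of panel MOIs."""
    out: Dict[str, List[str]] = {}
    for e in entries:
        out.setdefault(e.gene, [])
        if e.moi not in out[e.gene]:
            out[e.gene].append(e.moi)
    return {g: sorted(m) for g, m in out.items()}


def read_constraints(path) -> List[ConstraintScores]:
    df = pd.read_csv(path, sep="\t")
    out = []
    for _, row in df.iterrows():
        def opt(name):
            v = row.get(name)
            return None if v is None or pd.isna(v) else float(v)
        out.append(ConstraintScores(gene=str(row["gene"]), pli=opt("pli"),
                                    prec=opt("prec")))
    return out


def constraint_index(scores: Iterable[ConstraintScores]) -> Dict[str, ConstraintScores]:
    return {s.gene: s for s in scores}


def read_recurrence(path) -> Dict[str, int]:
    """gene -> number of additional carriers seen in external cohorts."""
    df = pd.read_csv(path, sep="\t")
    return {str(row["gene"]): int(row["carriers"]) for _, row in df.iterrows()}


# ---------------------------------------------------------------------------
# CNV call tables
# ---------------------------------------------------------------------------

def read_cnv_calls(path, caller: str) -> list:
    """Read one caller's BED-like CNV table (chrom, start, end, type,
    sample; 0-based half-open) into 1-based inclusive :class:`CnvCall`s.

    Rows with ``end <= start`` or an unknown type are rejected with a
    warning.
    """
    from .cnv_consensus import CnvCall  # late import avoids a cycle
    calls = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 5:
                raise FormatError(f"{path}: line {lineno}: expected 5 columns")
            chrom, start, end, cnv_type, sample = parts[:5]
            start, end = int(start), int(end)
            cnv_type = cnv_type.upper()
            if cnv_type in {"DELETION"}:
                cnv_type = "DEL"
            if cnv_type in {"DUPLICATION"}:
                cnv_type = "DUP"
            if end <= start:
                warnings.warn(f"{path}: line {lineno}: zero/negative length "
                              "interval rejected")
                continue
            if cnv_type not in {"DEL", "DUP"}:
                warnings.warn(f"{path}: line {lineno}: unknown CNV type "
                              f"{parts[3]!r} rejected")
                continue
            calls.append(CnvCall(sample_id=sample, chrom=chrom,
                                 start=start + 1, end=end,
                                 type=cnv_type, caller=caller))
    return calls


def write_cnv_calls(calls, path) -> None:
    """Write CnvCalls back to the 0-based half-open BED-like table."""
    with open(path, "w") as fh:
        for c in calls:
            fh.write(f"{c.chrom}\t{c.start - 1}\t{c.end}\t{c.type}\t{c.sample_id}\n")
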