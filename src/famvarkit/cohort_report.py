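"""Cohort-level yield tallies and the consanguinity-stratified burden test.

Works from a flat table of candidate rows — one per reported variant,
with family id, variant class (snv_indel / cnv / tre / mtdna),
inheritance, tier, ACMG label, and the family's consanguinity status —
plus cohort facts (family count, consanguineous count, proband sexes).
Rows in the same family with the same class and inheritance are one
*event* (e.g. two damaging variants on one homozygous haplotype).

The recessive burden comparison is a 2x2 of consanguineous vs
non-consanguineous families against carrying >= 1 known-gene homozygous
candidate; both the Pearson chi-square without continuity correction
and the two-sided Fisher exact p are always reported.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from decimal import Decimal, ROUND_HALF_UP
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import pandas as pd
from scipy import stats

VARIANT_CLASSES = ("snv_indel", "cnv", "tre", "mtdna")
CLASS_PRECEDENCE = ("snv_indel", "cnv", "tre", "mtdna")

_DOMINANT = {"de_novo", "inherited_dominant", "dominant", "inherited"}
_RECESSIVE = {"homozygous_recessive", "homozygous"}
_X_LINKED = {"x_linked_recessive", "x_linked"}
_PLP_LABELS = {"P", "LP", "P/LP", "LPS"}


def pct(numerator: float, denominator: float) -> float:
    """Percentage rounded to 1 decimal, half away from zero."""
    if denominator == 0:
        return 0.0
    value = Decimal(numerator) / Decimal(denominator) * 100
    return float(value.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


@dataclass(slots=True)
class CandidateRow:
    family_id: str
    variant_class: str            # snv_indel | cnv | tre | mtdna
    inheritance: str
    tier: str = "known_panel"
    gene: str = ""
    acmg: Optional[str] = None
    consanguineous: Optional[bool] = None

    def category(self) -> str:
        if self.inheritance in _DOMINANT:
            return "dominant"
        if self.inheritance in _RECESSIVE:
            return "recessive"
        if self.inheritance in _X_LINKED:
            return "x_linked"
        return "other"


@dataclass(slots=True)
class CohortFacts:
    n_families: int
    n_consanguineous: Optional[int] = None
    probands_male: Optional[int] = None
    probands_female: Optional[int] = None


@dataclass(slots=True)
class BurdenStats:
    chi2_statistic: Optional[float]
    chi2_p: Optional[float]
    fisher_p: float


@dataclass
class CohortSummary:
    facts: CohortFacts
    n_known_families: int = 0
    pct_known: float = 0.0
    category_family_counts: Dict[str, int] = field(default_factory=dict)
    category_family_pct: Dict[str, float] = field(default_factory=dict)
    dominant_class_split_pct: Dict[str, float] = field(default_factory=dict)
    class_family_counts: Dict[str, int] = field(default_factory=dict)
    class_family_pct: Dict[str, float] = field(default_factory=dict)
    snv_category_split_pct: Dict[str, float] = field(default_factory=dict)
    n_events: int = 0
    n_plp_events: int = 0
    pct_plp_events: float = 0.0
    burden_table: Optional[List[List[int]]] = None
    burden_stats: Optional[BurdenStats] = None
    recessive_yield_consanguineous_pct: Optional[float] = None
    recessive_yield_nonconsanguineous_pct: Optional[float] = None
    sex_ratio: Optional[float] = None
    family_primary_class: Dict[str, str] = field(default_factory=dict)

    def to_dict(self) -> dict:
        out = asdict(self)
        return out


# ---------------------------------------------------------------------------
# tally
# ---------------------------------------------------------------------------

def _events(rows: Sequence[CandidateRow]) -> List[Tuple[str, str, str, List[CandidateRow]]]:
    grouped: Dict[Tuple[str, str, str], List[CandidateRow]] = {}
    for row in rows:
        grouped.setdefault((row.family_id, row.variant_class, row.inheritance),
                           []).append(row)
    return [(f, c, i, rs) for (f, c, i), rs in grouped.items()]


def tally_yield(rows: Sequence[CandidateRow], facts: CohortFacts,
                known_families: Optional[Iterable[str]] = None,
                precedence: Sequence[str] = CLASS_PRECEDENCE) -> CohortSummary:
    """Aggregate known-panel candidate rows into the cohort summary.

    Families are counted once per category however many candidates of
    that category they carry.  ``known_families`` restricts which family
    ids are legal (defaults to accepting all); an unknown id raises.
    """
    if known_families is not None:
        legal = set(known_families)
        for row in rows:
            if row.family_id not in legal:
                raise KeyError(f"candidate references unknown family "
                               f"{row.family_id!r}")
    summary = CohortSummary(facts=facts)
    known_rows = [r for r in rows if r.tier == "known_panel"]
    events = _events(known_rows)
    families = sorted({r.family_id for r in known_rows})
    summary.n_known_families = len(families)
    summary.pct_known = pct(len(families), facts.n_families)
    summary.n_events = len(events)

    # families by inheritance category
    cat_fams: Dict[str, set] = {"dominant": set(), "recessive": set(),
                                "x_linked": set()}
    for fam, _, inh, rs in events:
        cat = rs[0].category()
        if cat in cat_fams:
            cat_fams[cat].add(fam)
    summary.category_family_counts = {k: len(v) for k, v in cat_fams.items()}
    summary.category_family_pct = {
        k: pct(len(v), summary.n_known_families) for k, v in cat_fams.items()}

    # class-of-variant split among dominant families (one primary class per
    # family by precedence, de novo before inherited within a class)
    dom_primary: Dict[str, str] = {}
    rank = {c: i for i, c in enumerate(precedence)}
    for fam, cls, inh, rs in events:
        if rs[0].category() != "dominant":
            continue
        if fam not in dom_primary or rank.get(cls, 99) < rank.get(dom_primary[fam], 99):
            dom_primary[fam] = cls
    n_dom = len(dom_primary)
    summary.dominant_class_split_pct = {
        cls: pct(sum(1 for v in dom_primary.values() if v == cls), n_dom)
        for cls in precedence}

    # families per variant class (a family counts once per class)
    cls_fams: Dict[str, set] = {c: set() for c in VARIANT_CLASSES}
    for fam, cls, _, _ in events:
        if cls in cls_fams:
            cls_fams[cls].add(fam)
    summary.class_family_counts = {c: len(v) for c, v in cls_fams.items()}
    summary.class_family_pct = {
        c: pct(len(v), summary.n_known_families) for c, v in cls_fams.items()}

    # inheritance split within SNV/indel families
    snv_cat: Dict[str, set] = {"dominant": set(), "recessive": set(),
                               "x_linked": set()}
    for fam, cls, inh, rs in events:
        if cls == "snv_indel" and rs[0].category() in snv_cat:
            snv_cat[rs[0].category()].add(fam)
    n_snv = len(cls_fams["snv_indel"])
    summary.snv_category_split_pct = {
        k: pct(len(v), n_snv) for k, v in snv_cat.items()}

    # ACMG pathogenic / likely-pathogenic events
    def plp(rs: List[CandidateRow]) -> bool:
        return any((r.acmg or "").upper() in _PLP_LABELS for r in rs)
    summary.n_plp_events = sum(1 for _, _, _, rs in events if plp(rs))
    summary.pct_plp_events = pct(summary.n_plp_events, summary.n_events)

    # primary class per family across everything (report convenience)
    for fam, cls, inh, rs in events:
        if (fam not in summary.family_primary_class
                or rank.get(cls, 99) < rank.get(summary.family_primary_class[fam], 99)):
            summary.family_primary_class[fam] = cls

    # recessive burden 2x2, restricted to families with known status
    if facts.n_consanguineous is not None:
        rec_consang = {fam for fam, cls, inh, rs in events
                       if cls == "snv_indel" and rs[0].category() == "recessive"
                       and rs[0].consanguineous is True}
        rec_noncons = {fam for fam, cls, inh, rs in events
                       if cls == "snv_indel" and rs[0].category() == "recessive"
                       and rs[0].consanguineous is False}
        n_con = facts.n_consanguineous
        n_non = facts.n_families - n_con
        table = [[len(rec_consang), n_con - len(rec_consang)],
                 [len(rec_noncons), n_non - len(rec_noncons)]]
        summary.burden_table = table
        summary.burden_stats = burden_test(table)
        summary.recessive_yield_consanguineous_pct = pct(len(rec_consang), n_con)
        summary.recessive_yield_nonconsanguineous_pct = pct(len(rec_noncons), n_non)

    if facts.probands_male is not None and facts.probands_female:
        summary.sex_ratio = round(facts.probands_male / facts.probands_female, 1)
    return summary


# ---------------------------------------------------------------------------
# burden test
# ---------------------------------------------------------------------------

def burden_test(table: Sequence[Sequence[int]]) -> BurdenStats:
    """Pearson chi-square (no continuity correction) and two-sided
    Fisher exact p for a 2x2 table.

    When a margin is zero the chi-square is undefined (reported as
    None); Fisher is always computed.
    """
    a, b = table[0]
    c, d = table[1]
    rows = (a + b, c + d)
    cols = (a + c, b + d)
    if 0 in rows or 0 in cols:
        chi2_stat = chi2_p = None
    else:
        res = stats.chi2_contingency([[a, b], [c, d]], correction=False)
        chi2_stat = float(res.statistic)
        chi2_p = float(res.pvalue)
    fisher_p = float(stats.fisher_exact([[a, b], [c, d]],
                                        alternative="two-sided")[1])
    return BurdenStats(chi2_statistic=chi2_stat, chi2_p=chi2_p,
                       fisher_p=fisher_p)


# ---------------------------------------------------------------------------
# fixture candidate tables
# ---------------------------------------------------------------------------

def read_candidate_table(path) -> List[CandidateRow]:
    """Read a candidate-row TSV (family_id, variant_class, inheritance,
    tier, gene, acmg, consanguineous)."""
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#").fillna("")
    rows = []
    for _, r in df.iterrows():
        consang = {"yes": True, "no": False}.get(str(r.get("consanguineous", "")).lower())
        rows.append(CandidateRow(
            family_id=r["family_id"],
            variant_class=r["variant_class"],
            inheritance=r["inheritance"],
            tier=r.get("tier") or "known_panel",
            gene=r.get("gene", ""),
            acmg=r.get("acmg") or None,
            consanguineous=consang,
        ))
    return rows


def fixture_path(name: str):
    """Path to a packaged reference table (e.g. ``table2.tsv``)."""
    from importlib.resources import files
    return files("famvarkit").joinpath("data", name)


def read_cohort_facts(path) -> CohortFacts:
    df = pd.read_csv(path, sep="\t", comment="#")
    row = df.iloc[0]
    def opt(name):
        return int(row[name]) if name in df.columns and not pd.isna(row[name]) else None
    return CohortFacts(n_families=int(row["n_families"]),
                       n_consanguineous=opt("n_consanguineous"),
                       probands_male=opt("probands_male"),
                       probands_female=opt("probands_female"))


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------

def render_report(summary: CohortSummary, path_prefix) -> Tuple[str, str]:
    """Write the summary as machine-readable JSON and a human TSV.

    Returns the two paths written (``<prefix>.json``, ``<prefix>.tsv``).
    """
    json_path = f"{path_prefix}.json"
    tsv_path = f"{path_prefix}.tsv"
    with open(json_path, "w") as fh:
        json.dump(summary.to_dict(), fh, indent=2, sort_keys=True)
    flat: List[Tuple[str, object]] = [
        ("n_families", summary.facts.n_families),
        ("families_with_known_panel_candidate", summary.n_known_families),
        ("pct_known", summary.pct_known),
        ("n_events", summary.n_events),
        ("n_plp_events", summary.n_plp_events),
        ("pct_plp_events", summary.pct_plp_events),
        ("sex_ratio", summary.sex_ratio),
    ]
    for k, v in sorted(summary.category_family_counts.items()):
        flat.append((f"families_{k}", v))
        flat.append((f"pct_{k}", summary.category_family_pct[k]))
    for k, v in sorted(summary.dominant_class_split_pct.items()):
        flat.append((f"dominant_split_pct_{k}", v))
    for k, v in sorted(summary.class_family_counts.items()):
        flat.append((f"families_class_{k}", v))
        flat.append((f"pct_class_{k}", summary.class_family_pct[k]))
    if summary.burden_table is not None:
        flat.append(("burden_table", json.dumps(summary.burden_table)))
        flat.append(("burden_chi2", summary.burden_stats.chi2_statistic))
        flat.append(("burden_chi2_p", summary.burden_stats.chi2_p))
        flat.append(("burden_fisher_p", summary.burden_stats.fisher_p))
        flat.append(("recessive_yield_consanguineous_pct",
                     summary.recessive_yield_consanguineous_pct))
        flat.append(("recessive_yield_nonconsanguineous_pct",
                     summary.recessive_yield_nonconsanguineous_pct))
    with open(tsv_path, "w") as fh:
        fh.write("metric\tvalue\n")
        for key, value in flat:
            fh.write(f"{key}\t{value}\n")
    return json_path, tsv_path


def load_report(json_path) -> dict:
    with open(json_path) as fh:
        return json.load(fh)
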