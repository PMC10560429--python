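"""Synthetic family cohorts with planted causal variants and truth labels.

The generator emulates the study design the pipeline targets: ~100
simplex/multiplex ASD families, a controllable consanguineous fraction
built from explicit first-cousin parental pairs (shared-grandparent
founders are simulated for genotype transmission and then dropped from
the emitted pedigree, so offspring expected inbreeding is F = 1/16), a
controllable complete-trio fraction, Hardy–Weinberg founder genotypes
over one pseudo-autosome plus one X chromosome, Mendelian transmission,
and planted causal variants of every class (de novo / inherited
dominant / homozygous recessive / X-linked / compound het SNVs, multi-
caller CNV call sets with coordinate jitter and caller-specific false
positives, TRE loci, and mtDNA heteroplasmy observations), each with a
truth record naming its expected inheritance class and tier.

Consanguineous families are always emitted as complete trios: the
kinship criterion that detects them needs both parents genotyped, and
ascertainment of both parents is what makes a family classifiable at
all.  Incomplete trios are therefore drawn from the non-consanguineous
pool (the father is dropped).

All randomness flows from ``CohortSpec.seed``; a fixed seed gives
byte-identical output files.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field as dc_field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Set, Tuple

import numpy as np

from .cnv_consensus import CnvCall, TreLocus, write_tre_table
from .io_formats import (ConstraintScores, Family, GenotypeTable, Member,
                         PanelEntry, Pedigree, PredictorProfile, VariantRecord,
                         write_cnv_calls, write_ped, write_panel, write_vcf)
from .mito_screen import MtObservation, write_mt_observations

SCENARIOS = ("de_novo_snv", "inherited_dominant", "homozygous_recessive",
             "x_linked", "compound_het", "de_novo_cnv", "homozygous_cnv",
             "tre_known", "mtdna")

CNV_CALLERS = ("cnvnator", "delly", "erds", "manta", "speedseq", "svaba")

AUTOSOME = "chr1"
CHRX = "chrX"
AUTOSOME_LEN = 248_956_422
CHRX_LEN = 156_040_895

# The cohort composition the generator reproduces by default.
DEFAULT_PLANT_PLAN: Dict[str, int] = {
    "de_novo_snv": 9,
    "inherited_dominant": 1,
    "homozygous_recessive": 7,
    "x_linked": 5,
    "de_novo_cnv": 1,
    "homozygous_cnv": 1,
    "tre_known": 2,
    "mtdna": 1,
}

DAMAGING_PREDICTORS = PredictorProfile(
    cadd_phred=25.0, sift="deleterious", pph2_hdiv="probably_damaging",
    pph2_hvar="probably_damaging", lrt="deleterious",
    mutation_assessor="high", mutation_taster="deleterious",
    mpc=1.8, provean="deleterious")


@dataclass
class CohortSpec:
    """Parameters of one synthetic cohort.

    Defaults mirror the reference study design: 100 families, 44%
    consanguineous, 79% complete trios, two multiplex families with
    three affected siblings each, a male:female proband ratio of about
    5.5, and the default plant plan of 27 known-gene causal events.
    50,000 autosomal background sites give the kinship estimator a
    standard error of roughly 0.003-0.004 — a comfortable margin around
    the 0.044 cutoff for first-cousin parental pairs (phi = 1/16).
    """

    n_families: int = 100
    consanguineous_fraction: float = 0.44
    trio_completeness: float = 0.79
    n_multiplex: int = 2
    unaffected_sibling_fraction: float = 0.65
    male_proband_fraction: float = 0.846   # 88 of 104 probands
    n_background_sites: int = 50_000
    n_x_sites: int = 2_000
    maf_range: Tuple[float, float] = (0.05, 0.5)
    mean_depth: int = 40
    genotype_error_rate: float = 0.0
    cnv_jitter: int = 100
    cnv_fp_rate: float = 0.05
    cnv_callers_per_plant: int = 3
    plant_plan: Dict[str, int] = dc_field(default_factory=lambda: dict(DEFAULT_PLANT_PLAN))
    n_recessive_in_consanguineous: Optional[int] = 6
    seed: int = 0

    def validate(self) -> None:
        if not 0.0 <= self.consanguineous_fraction <= 1.0:
            raise ValueError("consanguineous_fraction must be in [0, 1]")
        if not 0.0 <= self.trio_completeness <= 1.0:
            raise ValueError("trio_completeness must be in [0, 1]")
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must satisfy 0 < low <= high <= 0.5")
        for name, count in self.plant_plan.items():
            if name not in SCENARIOS:
                raise ValueError(f"unknown plant scenario {name!r}")
            if count < 0:
                raise ValueError(f"negative plant count for {name}")
        if self.n_background_sites < 1:
            raise ValueError("n_background_sites must be >= 1")


@dataclass(slots=True)
class TruthRecord:
    family_id: str
    scenario: str
    gene: str
    key: str
    expected_inheritance: str
    expected_tier: str


# ---------------------------------------------------------------------------
# gene universe
# ---------------------------------------------------------------------------

@dataclass
class GeneUniverse:
    """Synthetic gene panel, constraint scores, recurrence counts, and
    the interval lists used by the CNV/TRE overlap stages."""

    panel: List[PanelEntry]
    constraints: List[ConstraintScores]
    recurrence: Dict[str, int]
    known_regions: List[Tuple[str, int, int, str]]   # 1-based inclusive
    tre_genes: List[Tuple[str, int, int, str]]

    @classmethod
    def default(cls, n_dominant: int = 634, n_biallelic: int = 942,
                n_x_linked: int = 138, n_novel: int = 40) -> "GeneUniverse":
        panel: List[PanelEntry] = []
        constraints: List[ConstraintScores] = []
        for i in range(1, n_dominant + 1):
            g = f"PD{i:04d}"
            panel.append(PanelEntry(g, "dominant"))
            constraints.append(ConstraintScores(g, pli=0.995, prec=0.4))
        for i in range(1, n_biallelic + 1):
            g = f"PB{i:04d}"
            panel.append(PanelEntry(g, "biallelic"))
            constraints.append(ConstraintScores(g, pli=0.05, prec=0.96))
        for i in range(1, n_x_linked + 1):
            g = f"PX{i:04d}"
            panel.append(PanelEntry(g, "x_linked"))
            constraints.append(ConstraintScores(g, pli=0.6, prec=0.5))
        recurrence: Dict[str, int] = {}
        for i in range(1, n_novel + 1):
            g = f"NV{i:03d}"
            prec = 0.95 if i % 2 else 0.5
            constraints.append(ConstraintScores(g, pli=0.3, prec=prec))
            recurrence[g] = i % 4
        known_regions = [
            (AUTOSOME, 150_000_000 + j * 2_500_000,
             150_000_000 + j * 2_500_000 + 2_000_000 - 1, f"ASD_REGION_{j + 1:02d}")
            for j in range(10)]
        tre_genes = [
            (AUTOSOME, 180_000_000 + j * 100_000,
             180_000_000 + j * 100_000 + 50_000 - 1, f"TREG{j + 1:02d}")
            for j in range(57)]
        return cls(panel=panel, constraints=constraints, recurrence=recurrence,
                   known_regions=known_regions, tre_genes=tre_genes)


# ---------------------------------------------------------------------------
# pedigree simulation
# ---------------------------------------------------------------------------

@dataclass(slots=True)
class _Person:
    pid: str
    father: Optional[str]
    mother: Optional[str]
    sex: str
    affected: Optional[bool]
    visible: bool


@dataclass
class _FamilyPlan:
    family_id: str
    people: List[_Person]
    consanguineous: bool
    complete: bool
    multiplex: bool

    def visible_members(self) -> List[_Person]:
        return [p for p in self.people if p.visible]

    def probands(self) -> List[_Person]:
        return [p for p in self.people if p.visible and p.affected]

    def proband(self) -> _Person:
        return self.probands()[0]

    def father_id(self) -> str:
        return f"{self.family_id}_F"

    def mother_id(self) -> str:
        return f"{self.family_id}_M"

    def unaffected_sibs(self) -> List[_Person]:
        return [p for p in self.people if p.visible and p.affected is False
                and (p.father or p.mother)]


def _build_family_plans(spec: CohortSpec) -> List[_FamilyPlan]:
    rng = np.random.default_rng([spec.seed, 0])
    n = spec.n_families
    n_consang = int(round(spec.consanguineous_fraction * n))
    n_incomplete = int(round((1.0 - spec.trio_completeness) * n))
    fam_ids = [f"F{i + 1:03d}" for i in range(n)]
    consang_ids = set(rng.choice(fam_ids, size=n_consang, replace=False))
    outbred = [f for f in fam_ids if f not in consang_ids]
    if n_incomplete > len(outbred):
        raise ValueError("cannot make that many incomplete trios: "
                         "consanguineous families are kept complete")
    incomplete_ids = set(rng.choice(outbred, size=n_incomplete, replace=False))
    # multiplex families are consanguineous complete trios (three affected sibs)
    multiplex_pool = sorted(consang_ids) if n_consang >= spec.n_multiplex else fam_ids
    multiplex_ids = set(rng.choice(multiplex_pool, size=spec.n_multiplex,
                                   replace=False)) if spec.n_multiplex else set()

    plans: List[_FamilyPlan] = []
    for fid in fam_ids:
        consang = fid in consang_ids
        complete = fid not in incomplete_ids
        multiplex = fid in multiplex_ids
        people: List[_Person] = []
        father, mother = f"{fid}_F", f"{fid}_M"
        if consang:
            # hidden scaffold: shared grandparents GP1 x GP2 -> sibs S1, S2;
            # S1 x U1 -> father, S2 x U2 -> mother (first cousins)
            gp1, gp2 = f"{fid}_HGP1", f"{fid}_HGP2"
            s1, s2 = f"{fid}_HS1", f"{fid}_HS2"
            u1, u2 = f"{fid}_HU1", f"{fid}_HU2"
            people += [
                _Person(gp1, None, None, "male", None, False),
                _Person(gp2, None, None, "female", None, False),
                _Person(s1, gp1, gp2, "male", None, False),
                _Person(s2, gp1, gp2, "female", None, False),
                _Person(u1, None, None, "female", None, False),
                _Person(u2, None, None, "male", None, False),
                _Person(father, s1, u1, "male", False, True),
                _Person(mother, u2, s2, "female", False, True),
            ]
        else:
            people += [
                _Person(father, None, None, "male", False, complete),
                _Person(mother, None, None, "female", False, True),
            ]
        n_affected = 3 if multiplex else 1
        for k in range(n_affected):
            sex = "male" if rng.random() < spec.male_proband_fraction else "female"
            people.append(_Person(f"{fid}_P{k + 1}", father, mother, sex, True, True))
        if not multiplex and rng.random() < spec.unaffected_sibling_fraction:
            sex = "male" if rng.random() < 0.5 else "female"
            people.append(_Person(f"{fid}_S1", father, mother, sex, False, True))
        plans.append(_FamilyPlan(family_id=fid, people=people,
                                 consanguineous=consang, complete=complete,
                                 multiplex=multiplex))
    return plans


def _plans_to_pedigree(plans: Sequence[_FamilyPlan]) -> Pedigree:
    families = []
    for plan in plans:
        visible_ids = {p.pid for p in plan.visible_members()}
        members = []
        for p in plan.visible_members():
            members.append(Member(
                sample_id=p.pid, sex=p.sex, affected=p.affected,
                father_id=p.father if p.father in visible_ids else None,
                mother_id=p.mother if p.mother in visible_ids else None))
        families.append(Family(family_id=plan.family_id, members=members))
    return Pedigree(families=families)


def simulate_pedigrees(spec: CohortSpec) -> Pedigree:
    """Simulate family structures only (hidden cousin scaffolds dropped)."""
    spec.validate()
    return _plans_to_pedigree(_build_family_plans(spec))


# ---------------------------------------------------------------------------
# genotype simulation
# ---------------------------------------------------------------------------

def _simulate_matrices(people: Sequence[_Person], spec: CohortSpec,
                       rng: np.random.Generator
                       ) -> Tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, List[str]]:
    """Gene-drop simulation over all individuals (hidden ones included).

    Returns (autosomal genotypes, X genotypes, autosomal MAFs, X MAFs,
    visible sample order).  Genotypes are ALT allele counts; males carry
    a single X allele (0/1).
    """
    n_a = spec.n_background_sites
    n_x = spec.n_x_sites
    lo, hi = spec.maf_range
    p_a = rng.uniform(lo, hi, n_a)
    p_x = rng.uniform(lo, hi, n_x)

    auto: Dict[str, Tuple[np.ndarray, np.ndarray]] = {}
    xhap: Dict[str, List[np.ndarray]] = {}
    sex_of = {p.pid: p.sex for p in people}

    def founder_hap(p):
        return (rng.random(p.size) < p).astype(np.int8)

    def meiosis(haps: List[np.ndarray], size: int) -> np.ndarray:
        if len(haps) == 1:
            return haps[0]
        pick = rng.integers(0, 2, size)
        return np.where(pick == 0, haps[0], haps[1])

    for person in people:  # topological order by construction
        if person.father is None or person.mother is None:
            auto[person.pid] = (founder_hap(p_a), founder_hap(p_a))
            xhap[person.pid] = ([founder_hap(p_x)] if person.sex == "male"
                                else [founder_hap(p_x), founder_hap(p_x)])
        else:
            fa, mo = person.father, person.mother
            auto[person.pid] = (meiosis(list(auto[fa]), n_a),
                                meiosis(list(auto[mo]), n_a))
            maternal_x = meiosis(xhap[mo], n_x)
            if person.sex == "male":
                xhap[person.pid] = [maternal_x]
            else:
                paternal_x = xhap[fa][0]  # fathers pass their single X
                xhap[person.pid] = [paternal_x, maternal_x]

    visible = [p.pid for p in people if p.visible]
    g_auto = np.column_stack([auto[s][0] + auto[s][1] for s in visible]).astype(np.int8)
    g_x = np.column_stack([sum(xhap[s]).astype(np.int8) for s in visible])

    if spec.genotype_error_rate > 0:
        for g, n_alleles in ((g_auto, 2), (g_x, None)):
            err = rng.random(g.shape) < spec.genotype_error_rate
            noise = rng.integers(0, 3, g.shape).astype(np.int8)
            if n_alleles is None:  # X: respect per-sample ploidy
                male_cols = np.array([sex_of[s] == "male" for s in visible])
                noise[:, male_cols] = np.clip(noise[:, male_cols], 0, 1)
            g[err] = noise[err]
    return g_auto, g_x, p_a, p_x, visible


def _quality_arrays(g: np.ndarray, spec: CohortSpec, rng: np.random.Generator,
                    hemizygous_cols: Optional[np.ndarray] = None):
    """Draw GQ/DP/AD consistent with the genotypes (clean sites pass QC)."""
    dp = rng.poisson(spec.mean_depth, g.shape).astype(np.int32)
    np.maximum(dp, 1, out=dp)
    gq = rng.integers(60, 100, g.shape, dtype=np.int32)
    ad_alt = np.zeros(g.shape, dtype=np.int32)
    het = g == 1
    if hemizygous_cols is not None:
        hemi = np.zeros(g.shape, dtype=bool)
        hemi[:, hemizygous_cols] = True
        hemi &= het
        het = het & ~hemi
        ad_alt[hemi] = dp[hemi]
    ad_alt[het] = rng.binomial(dp[het], 0.5)
    hom = g == 2
    ad_alt[hom] = dp[hom]
    ad_ref = dp - ad_alt
    return gq, dp, ad_ref, ad_alt


def _records_from_matrix(g: np.ndarray, positions: np.ndarray, chrom: str,
                         mafs: np.ndarray, samples: Tuple[str, ...],
                         spec: CohortSpec, rng: np.random.Generator,
                         male_cols: Optional[np.ndarray]) -> List[VariantRecord]:
    gq, dp, ad_ref, ad_alt = _quality_arrays(g, spec, rng, male_cols)
    af_dbs = ("1000g", "gnomad", "exac", "qgp", "internal")
    records = []
    for i in range(g.shape[0]):
        table = GenotypeTable(samples, g[i], gq[i], dp[i], ad_ref[i], ad_alt[i])
        records.append(VariantRecord(
            chrom=chrom, pos=int(positions[i]), ref="A", alt="G",
            consequence="other",
            pop_afs={db: float(mafs[i]) for db in af_dbs},
            genotypes=table))
    return records


def simulate_genotypes(pedigree: Pedigree, spec: CohortSpec) -> List[VariantRecord]:
    """Background variant records for an arbitrary pedigree.

    Members without in-pedigree parents are treated as unrelated
    founders drawn from Hardy–Weinberg proportions; children follow
    Mendelian transmission.  (The cousin scaffolds of consanguineous
    families only exist inside :func:`simulate_cohort`, which simulates
    the extended pedigree before dropping hidden members.)
    """
    spec.validate()
    people = []
    for fam in pedigree.families:
        ids = set(fam.ids())
        for m in fam.members:
            people.append(_Person(
                m.sample_id,
                m.father_id if m.father_id in ids else None,
                m.mother_id if m.mother_id in ids else None,
                m.sex, m.affected, True))
    rng = np.random.default_rng([spec.seed, 1])
    g_auto, g_x, p_a, p_x, visible = _simulate_matrices(people, spec, rng)
    return _assemble_background(g_auto, g_x, p_a, p_x, visible, people, spec, rng)


def _background_positions(spec: CohortSpec) -> Tuple[np.ndarray, np.ndarray]:
    pos_a = 10_000 + 1_000 * np.arange(spec.n_background_sites)
    pos_x = 3_000_000 + 500 * np.arange(spec.n_x_sites)
    return pos_a, pos_x


def _assemble_background(g_auto, g_x, p_a, p_x, visible, people, spec, rng
                         ) -> List[VariantRecord]:
    samples = tuple(visible)
    male_cols = np.array([p.sex == "male" for p in people if p.visible])
    pos_a, pos_x = _background_positions(spec)
    records = _records_from_matrix(g_auto.copy(), pos_a, AUTOSOME, p_a,
                                   samples, spec, rng, None)
    records += _records_from_matrix(g_x.copy(), pos_x, CHRX, p_x,
                                    samples, spec, rng, np.where(male_cols)[0])
    return records


# ---------------------------------------------------------------------------
# planting
# ---------------------------------------------------------------------------

@dataclass
class SyntheticCohort:
    """Everything one simulated cohort produces, plus its truth labels."""

    spec: CohortSpec
    pedigree: Pedigree
    records: List[VariantRecord]
    cnv_callsets: Dict[str, List[CnvCall]]
    cnv_af_reference: List[Tuple[str, int, int, str, float]]
    tre_loci: List[TreLocus]
    mt_observations: List[MtObservation]
    universe: GeneUniverse
    truth: List[TruthRecord]
    consanguineous_families: Set[str]
    lcr_intervals: List[Tuple[str, int, int]]   # 0-based half-open

    def write(self, outdir) -> Dict[str, Path]:
        """Emit every input file the pipeline reads, plus the truth table."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths: Dict[str, Path] = {}

        paths["vcf"] = outdir / "cohort.vcf"
        write_vcf(self.records, paths["vcf"],
                  contig_lengths={AUTOSOME: AUTOSOME_LEN, CHRX: CHRX_LEN})
        paths["ped"] = outdir / "cohort.ped"
        write_ped(self.pedigree, paths["ped"])
        paths["panel"] = outdir / "panel.tsv"
        write_panel(self.universe.panel, paths["panel"])
        paths["constraints"] = outdir / "constraints.tsv"
        with open(paths["constraints"], "w") as fh:
            fh.write("gene\tpli\tprec\n")
            for c in self.universe.constraints:
                fh.write(f"{c.gene}\t{c.pli}\t{c.prec}\n")
        paths["recurrence"] = outdir / "recurrence.tsv"
        with open(paths["recurrence"], "w") as fh:
            fh.write("gene\tcarriers\n")
            for gene, count in self.universe.recurrence.items():
                fh.write(f"{gene}\t{count}\n")
        for caller, calls in self.cnv_callsets.items():
            paths[f"cnv_{caller}"] = outdir / f"cnv_{caller}.tsv"
            write_cnv_calls(calls, paths[f"cnv_{caller}"])
        paths["cnv_af"] = outdir / "cnv_af_reference.tsv"
        with open(paths["cnv_af"], "w") as fh:
            for chrom, start, end, cnv_type, af in self.cnv_af_reference:
                fh.write(f"{chrom}\t{start - 1}\t{end}\t{cnv_type}\t{af}\n")
        paths["tre"] = outdir / "tre.tsv"
        write_tre_table(self.tre_loci, paths["tre"])
        paths["mtdna"] = outdir / "mtdna.tsv"
        write_mt_observations(self.mt_observations, paths["mtdna"])
        paths["known_regions"] = outdir / "known_regions.bed"
        with open(paths["known_regions"], "w") as fh:
            for chrom, start, end, name in self.universe.known_regions:
                fh.write(f"{chrom}\t{start - 1}\t{end}\t{name}\n")
        paths["tre_genes"] = outdir / "tre_genes.bed"
        with open(paths["tre_genes"], "w") as fh:
            for chrom, start, end, name in self.universe.tre_genes:
                fh.write(f"{chrom}\t{start - 1}\t{end}\t{name}\n")
        paths["lcr"] = outdir / "lcr.bed"
        with open(paths["lcr"], "w") as fh:
            for chrom, start, end in self.lcr_intervals:
                fh.write(f"{chrom}\t{start}\t{end}\n")
        paths["truth"] = outdir / "truth.tsv"
        with open(paths["truth"], "w") as fh:
            fh.write("family_id\tscenario\tgene\tkey\texpected_inheritance\t"
                     "expected_tier\n")
            for t in self.truth:
                fh.write(f"{t.family_id}\t{t.scenario}\t{t.gene}\t{t.key}\t"
                         f"{t.expected_inheritance}\t{t.expected_tier}\n")
            for fid in sorted(self.consanguineous_families):
                fh.write(f"{fid}\tconsanguineous_family\t\t\t\t\n")
        return paths


class PlantError(ValueError):
    """No eligible family remains for a requested plant scenario."""


def _draw_family(pool: List[_FamilyPlan], used: Set[str],
                 rng: np.random.Generator, scenario: str) -> _FamilyPlan:
    eligible = [f for f in pool if f.family_id not in used]
    if not eligible:
        raise PlantError(f"no eligible family left for scenario {scenario!r} "
                         f"(pool size {len(pool)}, all used)")
    plan = eligible[rng.integers(0, len(eligible))]
    used.add(plan.family_id)
    return plan


def _planted_site(samples: Tuple[str, ...], chrom: str, pos: int,
                  carrier_counts: Dict[str, int], consequence: str,
                  gene: str, spec: CohortSpec, male_hemi: Sequence[str] = ()
                  ) -> VariantRecord:
    n = len(samples)
    idx = {s: i for i, s in enumerate(samples)}
    g = np.zeros(n, dtype=np.int8)
    for sid, count in carrier_counts.items():
        g[idx[sid]] = count
    dp = np.full(n, spec.mean_depth, dtype=np.int32)
    gq = np.full(n, 99, dtype=np.int32)
    ad_alt = np.zeros(n, dtype=np.int32)
    ad_alt[g == 1] = spec.mean_depth // 2
    ad_alt[g == 2] = spec.mean_depth
    for sid in male_hemi:
        if carrier_counts.get(sid) == 1:
            ad_alt[idx[sid]] = spec.mean_depth
    ad_ref = dp - ad_alt
    table = GenotypeTable(samples, g, gq, dp, ad_ref, ad_alt)
    predictors = DAMAGING_PREDICTORS if consequence == "missense" else PredictorProfile()
    return VariantRecord(chrom=chrom, pos=pos, ref="C", alt="T",
                         consequence=consequence, gene=gene,
                         pop_afs={}, predictors=predictors, genotypes=table)


def plant_variants(plans: Sequence[_FamilyPlan], samples: Tuple[str, ...],
                   universe: GeneUniverse, spec: CohortSpec,
                   rng: np.random.Generator):
    """Plant every requested scenario; returns (snv records, per-caller
    CNV callsets, TRE loci, mtDNA observations, truth records)."""
    plan_by_id = {p.family_id: p for p in plans}
    complete = [p for p in plans if p.complete and not p.multiplex]
    complete_male = [p for p in complete if p.proband().sex == "male"]
    consang = [p for p in plans if p.consanguineous and not p.multiplex]
    nonconsang_any = [p for p in plans if not p.consanguineous]
    multiplex = [p for p in plans if p.multiplex]

    used: Set[str] = set()
    records: List[VariantRecord] = []
    truth: List[TruthRecord] = []
    callsets: Dict[str, List[CnvCall]] = {c: [] for c in CNV_CALLERS}
    tre_loci: List[TreLocus] = []
    mt_obs: List[MtObservation] = []

    dominant_genes = [e.gene for e in universe.panel if e.moi == "dominant"]
    biallelic_genes = [e.gene for e in universe.panel if e.moi == "biallelic"]
    x_genes = [e.gene for e in universe.panel if e.moi == "x_linked"]
    gene_cursor = {"dominant": 0, "biallelic": 0, "x_linked": 0}

    def next_gene(pool_name: str) -> str:
        pool = {"dominant": dominant_genes, "biallelic": biallelic_genes,
                "x_linked": x_genes}[pool_name]
        i = gene_cursor[pool_name]
        gene_cursor[pool_name] = i + 1
        return pool[i]

    next_pos = {"auto": 60_000_000, "x": 60_000_000}

    def alloc_pos(where: str) -> int:
        pos = next_pos[where]
        next_pos[where] += 10_000
        return pos

    plan = spec.plant_plan

    # ---- inherited dominant (multiplex segregation) -----------------------
    for k in range(plan.get("inherited_dominant", 0)):
        fam = _draw_family(multiplex, used, rng, "inherited_dominant")
        gene = next_gene("dominant")
        pos = alloc_pos("auto")
        carriers = {p.pid: 1 for p in fam.probands()}
        carriers[fam.father_id()] = 1
        records.append(_planted_site(samples, AUTOSOME, pos, carriers,
                                     "missense", gene, spec))
        truth.append(TruthRecord(fam.family_id, "inherited_dominant", gene,
                                 f"{AUTOSOME}:{pos}:C:T",
                                 "inherited_dominant", "known_panel"))

    # ---- X-linked recessive ----------------------------------------------
    for k in range(plan.get("x_linked", 0)):
        fam = _draw_family(complete_male, used, rng, "x_linked")
        gene = next_gene("x_linked")
        pos = alloc_pos("x")
        carriers = {fam.proband().pid: 1, fam.mother_id(): 1}
        records.append(_planted_site(samples, CHRX, pos, carriers, "missense",
                                     gene, spec, male_hemi=[fam.proband().pid]))
        truth.append(TruthRecord(fam.family_id, "x_linked", gene,
                                 f"{CHRX}:{pos}:C:T",
                                 "x_linked_recessive", "known_panel"))

    # ---- homozygous recessive --------------------------------------------
    n_rec = plan.get("homozygous_recessive", 0)
    n_in_consang = spec.n_recessive_in_consanguineous
    if n_in_consang is None:
        n_in_consang = min(n_rec, len([p for p in consang
                                       if p.family_id not in used]))
    nonconsang_complete = [p for p in nonconsang_any if p.complete]
    for k in range(n_rec):
        pool = consang if k < n_in_consang else nonconsang_complete
        fam = _draw_family(pool, used, rng, "homozygous_recessive")
        gene = next_gene("biallelic")
        pos = alloc_pos("auto")
        consequence = "stop_gained" if k == 0 else "missense"
        carriers = {fam.proband().pid: 2,
                    fam.father_id(): 1, fam.mother_id(): 1}
        for sib in fam.unaffected_sibs():
            carriers[sib.pid] = 1
        records.append(_planted_site(samples, AUTOSOME, pos, carriers,
                                     consequence, gene, spec))
        truth.append(TruthRecord(fam.family_id, "homozygous_recessive", gene,
                                 f"{AUTOSOME}:{pos}:C:T",
                                 "homozygous_recessive", "known_panel"))

    # ---- de novo SNVs -----------------------------------------------------
    for k in range(plan.get("de_novo_snv", 0)):
        fam = _draw_family(complete, used, rng, "de_novo_snv")
        gene = next_gene("dominant")
        pos = alloc_pos("auto")
        consequence = "frameshift_insertion" if k == 0 else "missense"
        carriers = {fam.proband().pid: 1}
        records.append(_planted_site(samples, AUTOSOME, pos, carriers,
                                     consequence, gene, spec))
        truth.append(TruthRecord(fam.family_id, "de_novo_snv", gene,
                                 f"{AUTOSOME}:{pos}:C:T",
                                 "de_novo", "known_panel"))

    # ---- compound heterozygotes ------------------------------------------
    for k in range(plan.get("compound_het", 0)):
        fam = _draw_family(complete, used, rng, "compound_het")
        gene = next_gene("biallelic")
        pos1, pos2 = alloc_pos("auto"), alloc_pos("auto")
        records.append(_planted_site(
            samples, AUTOSOME, pos1,
            {fam.proband().pid: 1, fam.father_id(): 1}, "missense", gene, spec))
        records.append(_planted_site(
            samples, AUTOSOME, pos2,
            {fam.proband().pid: 1, fam.mother_id(): 1}, "missense", gene, spec))
        truth.append(TruthRecord(
            fam.family_id, "compound_het", gene,
            f"{AUTOSOME}:{pos1}:C:T|{AUTOSOME}:{pos2}:C:T",
            "compound_het", "known_panel"))

    # ---- CNVs -------------------------------------------------------------
    def emit_cnv(fam: _FamilyPlan, carriers: List[str], start: int, end: int,
                 cnv_type: str) -> None:
        caller_idx = rng.choice(len(CNV_CALLERS),
                                size=spec.cnv_callers_per_plant, replace=False)
        for ci in caller_idx:
            caller = CNV_CALLERS[ci]
            for sid in carriers:
                js = int(rng.integers(-spec.cnv_jitter, spec.cnv_jitter + 1)) \
                    if spec.cnv_jitter else 0
                je = int(rng.integers(-spec.cnv_jitter, spec.cnv_jitter + 1)) \
                    if spec.cnv_jitter else 0
                callsets[caller].append(CnvCall(
                    sample_id=sid, chrom=AUTOSOME,
                    start=start + js, end=max(end + je, start + js + 1),
                    type=cnv_type, caller=caller))

    region_cursor = 0
    for k in range(plan.get("de_novo_cnv", 0)):
        fam = _draw_family(complete, used, rng, "de_novo_cnv")
        chrom, rs, re_, name = universe.known_regions[region_cursor]
        region_cursor += 1
        start, end = rs + 50_000, rs + 50_000 + 1_400_000 - 1
        emit_cnv(fam, [fam.proband().pid], start, end, "DEL")
        truth.append(TruthRecord(fam.family_id, "de_novo_cnv", name,
                                 f"{chrom}:{start}-{end}:DEL",
                                 "de_novo", "known_panel"))

    for k in range(plan.get("homozygous_cnv", 0)):
        fam = _draw_family(complete, used, rng, "homozygous_cnv")
        chrom, rs, re_, name = universe.known_regions[region_cursor]
        region_cursor += 1
        start, end = rs + 20_000, rs + 20_000 + 5_000 - 1
        emit_cnv(fam, [fam.proband().pid, fam.father_id(), fam.mother_id()],
                 start, end, "DEL")
        truth.append(TruthRecord(fam.family_id, "homozygous_cnv", name,
                                 f"{chrom}:{start}-{end}:DEL",
                                 "homozygous", "known_panel"))

    # caller-specific false positives: each caller draws singleton calls in
    # its own coordinate lane, so no two callers can corroborate an artifact
    n_fp = int(spec.cnv_fp_rate * len(samples))
    for ci, caller in enumerate(CNV_CALLERS):
        lane = 70_000_000 + ci * 10_000_000
        for _ in range(n_fp):
            sid = samples[rng.integers(0, len(samples))]
            start = lane + int(rng.integers(0, 9_000_000))
            length = int(rng.integers(1_000, 50_000))
            callsets[caller].append(CnvCall(
                sample_id=sid, chrom=AUTOSOME, start=start,
                end=start + length, type="DEL" if rng.random() < 0.5 else "DUP",
                caller=caller))

    # ---- TREs -------------------------------------------------------------
    for k in range(plan.get("tre_known", 0)):
        fam = _draw_family(list(plans), used, rng, "tre_known")
        chrom, gs, ge, gene = universe.tre_genes[k]
        locus = TreLocus(chrom=chrom, start=gs + 1_000, end=gs + 1_600,
                         motif="AAAAT", carriers={fam.proband().pid})
        tre_loci.append(locus)
        truth.append(TruthRecord(fam.family_id, "tre_known", gene,
                                 f"{chrom}:{locus.start}-{locus.end}:TRE",
                                 "na", "known_panel"))
    # decoy TRE outside any known TRE gene
    if tre_loci:
        tre_loci.append(TreLocus(chrom=AUTOSOME, start=95_000_000,
                                 end=95_000_600, motif="CAG",
                                 carriers={plans[0].proband().pid}))

    # ---- mtDNA ------------------------------------------------------------
    for k in range(plan.get("mtdna", 0)):
        fam = _draw_family(complete, used, rng, "mtdna")
        proband = fam.proband().pid
        mt_obs.append(MtObservation(proband, 3243, "A", "G", 979, 21))
        mt_obs.append(MtObservation(fam.mother_id(), 3243, "A", "G", 1000, 0))
        truth.append(TruthRecord(fam.family_id, "mtdna", "MT-TL1",
                                 "MT:3243:A:G", "de_novo", "known_panel"))

    af_reference = [
        (AUTOSOME, 130_000_000, 130_050_000, "DEL", 0.05),
        (AUTOSOME, 131_000_000, 131_020_000, "DUP", 0.12),
    ]
    return records, callsets, tre_loci, mt_obs, truth, af_reference


# ---------------------------------------------------------------------------
# full cohort
# ---------------------------------------------------------------------------

def simulate_cohort(spec: CohortSpec,
                    universe: Optional[GeneUniverse] = None) -> SyntheticCohort:
    """Simulate pedigrees, background genotypes, and planted variants."""
    spec.validate()
    if universe is None:
        # a compact panel keeps file sizes sensible; membership logic is
        # unaffected by panel size
        universe = GeneUniverse.default(n_dominant=40, n_biallelic=40,
                                        n_x_linked=12, n_novel=20)
    plans = _build_family_plans(spec)
    people = [p for plan in plans for p in plan.people]
    rng_geno = np.random.default_rng([spec.seed, 1])
    g_auto, g_x, p_a, p_x, visible = _simulate_matrices(people, spec, rng_geno)
    records = _assemble_background(g_auto, g_x, p_a, p_x, visible, people,
                                   spec, rng_geno)
    samples = tuple(visible)
    rng_plant = np.random.default_rng([spec.seed, 2])
    planted, callsets, tre_loci, mt_obs, truth, af_ref = plant_variants(
        plans, samples, universe, spec, rng_plant)
    records = records + planted
    pedigree = _plans_to_pedigree(plans)
    # low-complexity decoy mask over the first handful of background sites
    lcr = [(AUTOSOME, 9_999, 20_000)]
    return SyntheticCohort(
        spec=spec, pedigree=pedigree, records=records,
        cnv_callsets=callsets, cnv_af_reference=af_ref, tre_loci=tre_loci,
        mt_observations=mt_obs, universe=universe, truth=truth,
        consanguineous_families={p.family_id for p in plans if p.consanguineous},
        lcr_intervals=lcr)


def read_truth(path) -> Tuple[List[TruthRecord], Set[str]]:
    """Read a truth TSV back; returns (planted events, consanguineous ids)."""
    events: List[TruthRecord] = []
    consang: Set[str] = set()
    with open(path) as fh:
        fh.readline()
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if parts[1] == "consanguineous_family":
                consang.add(parts[0])
            else:
                events.append(TruthRecord(*parts[:6]))
    return events, consang
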