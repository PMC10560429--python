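"""End-to-end orchestration: inputs -> candidates -> cohort summary.

Runs the stages in method order — relatedness and consanguinity flags,
SNV/indel prioritization, CNV consensus + inheritance + known-overlap,
TRE matching, mitochondrial screening — then flattens everything into
candidate rows and the cohort summary.  The per-stage record counts
(the attrition funnel) are logged at INFO level.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence, Set, Tuple

from .cnv_consensus import (CnvCall, ConsensusCnv, TreLocus, cnv_inheritance,
                            consensus_and_merge, overlap_known,
                            read_region_intervals, read_tre_table, tre_overlap)
from .cohort_report import (CandidateRow, CohortFacts, CohortSummary,
                            tally_yield)
from .config import PipelineConfig, DEFAULT_CONFIG
from .io_formats import (ConstraintScores, PanelEntry, Pedigree, VariantRecord,
                         constraint_index, panel_index, read_bed,
                         read_cnv_calls, read_constraints, read_panel,
                         read_ped, read_recurrence, read_vcf)
from .mito_screen import (DEFAULT_KNOWN_VARIANTS, MtHit, MtKnownVariant,
                          MtObservation, read_mt_known, read_mt_observations,
                          screen_mtdna)
from .relatedness import (InbreedingEstimate, KinshipEstimate,
                          estimate_relatedness)
from .snv_prioritizer import CandidateVariant, prioritize

log = logging.getLogger(__name__)


@dataclass
class PipelineInputs:
    """Everything one cohort analysis consumes, already in memory."""

    records: List[VariantRecord]
    pedigree: Pedigree
    panel: List[PanelEntry]
    constraints: List[ConstraintScores]
    recurrence: Dict[str, int]
    cnv_callsets: Dict[str, List[CnvCall]] = field(default_factory=dict)
    cnv_af_reference: List[Tuple[str, int, int, str, float]] = field(default_factory=list)
    known_regions: List[Tuple[str, int, int, str]] = field(default_factory=list)
    tre_loci: List[TreLocus] = field(default_factory=list)
    tre_genes: List[Tuple[str, int, int, str]] = field(default_factory=list)
    mt_observations: List[MtObservation] = field(default_factory=list)
    mt_known: Sequence[MtKnownVariant] = DEFAULT_KNOWN_VARIANTS
    config: PipelineConfig = field(default_factory=lambda: DEFAULT_CONFIG)

    @classmethod
    def from_files(cls, *, vcf, ped, panel, constraints, recurrence,
                   lcr_bed=None, cnv_tables: Optional[Mapping[str, str]] = None,
                   cnv_af_reference=None, known_regions_bed=None,
                   tre_table=None, tre_genes_bed=None, mt_table=None,
                   mt_known=None, config: Optional[PipelineConfig] = None
                   ) -> "PipelineInputs":
        cfg = config or DEFAULT_CONFIG
        mask = read_bed(lcr_bed) if lcr_bed else None
        callsets = {caller: read_cnv_calls(path, caller)
                    for caller, path in (cnv_tables or {}).items()}
        af_ref = []
        if cnv_af_reference:
            with open(cnv_af_reference) as fh:
                for line in fh:
                    line = line.strip()
                    if not line or line.startswith("#"):
                        continue
                    chrom, start, end, cnv_type, af = line.split("\t")[:5]
                    af_ref.append((chrom, int(start) + 1, int(end),
                                   cnv_type, float(af)))
        return cls(
            records=read_vcf(vcf, lcr_mask=mask, field_map=cfg.fields),
            pedigree=read_ped(ped),
            panel=read_panel(panel),
            constraints=read_constraints(constraints),
            recurrence=read_recurrence(recurrence),
            cnv_callsets=callsets,
            cnv_af_reference=af_ref,
            known_regions=read_region_intervals(known_regions_bed)
            if known_regions_bed else [],
            tre_loci=read_tre_table(tre_table) if tre_table else [],
            tre_genes=read_region_intervals(tre_genes_bed)
            if tre_genes_bed else [],
            mt_observations=read_mt_observations(mt_table) if mt_table else [],
            mt_known=read_mt_known(mt_known) if mt_known
            else DEFAULT_KNOWN_VARIANTS,
            config=cfg,
        )


@dataclass
class PipelineResult:
    pedigree: Pedigree
    kinships: List[KinshipEstimate]
    inbreedings: List[InbreedingEstimate]
    consanguinity_report: Dict[str, Dict[str, object]]
    snv_candidates: List[CandidateVariant]
    consensus_cnvs: List[ConsensusCnv]
    family_cnvs: Dict[str, List[ConsensusCnv]]
    tre_matches: List[Tuple[TreLocus, List[str]]]
    mt_hits: List[MtHit]
    rows: List[CandidateRow]
    summary: CohortSummary

    def consanguineous_families(self) -> Set[str]:
        return {f.family_id for f in self.pedigree.families if f.consanguineous}


def _family_of_sample(pedigree: Pedigree) -> Dict[str, str]:
    return {m.sample_id: fam.family_id
            for fam in pedigree.families for m in fam.members}


_CNV_INHERITANCE_ROW = {"de_novo": "de_novo", "homozygous": "homozygous_recessive",
                        "inherited": "inherited_dominant"}


def run_pipeline(inputs: PipelineInputs) -> PipelineResult:
    cfg = inputs.config
    th = cfg.thresholds
    ped = inputs.pedigree
    fam_of = _family_of_sample(ped)
    consang_flag: Dict[str, Optional[bool]] = {}

    # --- relatedness ------------------------------------------------------
    kinships, inbreedings, consang_report = estimate_relatedness(
        inputs.records, ped, th)
    for fam in ped.families:
        consang_flag[fam.family_id] = fam.consanguineous
    log.info("relatedness: %d parental pairs, %d inbreeding estimates, "
             "%d consanguineous families", len(kinships), len(inbreedings),
             sum(1 for f in ped.families if f.consanguineous))

    # --- SNV / indel cascade ---------------------------------------------
    log.info("funnel: %d input records", len(inputs.records))
    panel_idx = panel_index(inputs.panel)
    constraint_idx = constraint_index(inputs.constraints)
    snv_candidates = prioritize(inputs.records, ped, panel_idx,
                                constraint_idx, inputs.recurrence, th)
    log.info("funnel: %d tiered SNV/indel candidates", len(snv_candidates))

    # --- CNVs -------------------------------------------------------------
    consensus = consensus_and_merge(inputs.cnv_callsets, window=th.cnv_window,
                                    min_callers=th.cnv_min_callers)
    overlap_known(consensus, inputs.known_regions)
    family_cnvs: Dict[str, List[ConsensusCnv]] = {}
    for fam in ped.families:
        annotated = cnv_inheritance(consensus, fam, inputs.cnv_af_reference, th)
        if annotated:
            family_cnvs[fam.family_id] = annotated
    log.info("funnel: %d consensus CNVs, %d families with CNV calls",
             len(consensus), len(family_cnvs))

    # --- TREs -------------------------------------------------------------
    tre_matches = tre_overlap(inputs.tre_loci, inputs.tre_genes)

    # --- mtDNA ------------------------------------------------------------
    mt_hits = screen_mtdna(inputs.mt_observations, inputs.mt_known,
                           th.heteroplasmy_min, ped)

    # --- flatten to candidate rows ---------------------------------------
    rows: List[CandidateRow] = []
    for cand in snv_candidates:
        rows.append(CandidateRow(
            family_id=cand.family_id, variant_class="snv_indel",
            inheritance=cand.inheritance, tier=cand.tier or "",
            gene=cand.variant.gene or "", acmg=cand.acmg_label,
            consanguineous=consang_flag.get(cand.family_id)))
    for fam_id, cnvs in family_cnvs.items():
        for cnv in cnvs:
            if cnv.inheritance is None:
                continue
            rows.append(CandidateRow(
                family_id=fam_id, variant_class="cnv",
                inheritance=_CNV_INHERITANCE_ROW[cnv.inheritance],
                tier="known_panel" if cnv.known_label == "known"
                else "novel_candidate",
                gene=",".join(cnv.overlapped), acmg=None,
                consanguineous=consang_flag.get(fam_id)))
    for locus, genes in tre_matches:
        for carrier in sorted(locus.carriers):
            fam_id = fam_of.get(carrier)
            if fam_id is None:
                continue
            rows.append(CandidateRow(
                family_id=fam_id, variant_class="tre", inheritance="dominant",
                tier="known_panel", gene=",".join(genes), acmg=None,
                consanguineous=consang_flag.get(fam_id)))
    for hit in mt_hits:
        if hit.unevaluable or not hit.is_proband:
            continue
        fam_id = fam_of.get(hit.observation.sample_id)
        if fam_id is None:
            continue
        rows.append(CandidateRow(
            family_id=fam_id, variant_class="mtdna",
            inheritance="de_novo" if hit.de_novo_heteroplasmy else "inherited",
            tier="known_panel", gene=hit.known.disorder, acmg=None,
            consanguineous=consang_flag.get(fam_id)))

    # --- cohort facts & summary ------------------------------------------
    probands = [m for fam in ped.families for m in fam.members
                if m.affected and (m.father_id or m.mother_id)]
    facts = CohortFacts(
        n_families=len(ped.families),
        n_consanguineous=sum(1 for f in ped.families if f.consanguineous),
        probands_male=sum(1 for p in probands if p.sex == "male"),
        probands_female=sum(1 for p in probands if p.sex == "female"))
    summary = tally_yield(rows, facts,
                          known_families=[f.family_id for f in ped.families])
    return PipelineResult(
        pedigree=ped, kinships=kinships, inbreedings=inbreedings,
        consanguinity_report=consang_report, snv_candidates=snv_candidates,
        consensus_cnvs=consensus, family_cnvs=family_cnvs,
        tre_matches=tre_matches, mt_hits=mt_hits, rows=rows, summary=summary)


# ---------------------------------------------------------------------------
# truth-set evaluation (synthetic cohorts)
# ---------------------------------------------------------------------------

def _parse_interval_key(key: str) -> Tuple[str, int, int, str]:
    loc, cnv_type = key.rsplit(":", 1)
    chrom, span = loc.split(":")
    start, end = span.split("-")
    return chrom, int(start), int(end), cnv_type


def evaluate_recovery(result: PipelineResult, truth_events,
                      consang_truth: Set[str]) -> Dict[str, object]:
    """Compare pipeline output against planted truth.

    Returns per-event hit/miss details, overall sensitivity, the number
    of false-positive causal calls in families/genes with no plant, and
    the symmetric difference of consanguinity flags.
    """
    snv_by_family: Dict[str, List[CandidateVariant]] = {}
    for cand in result.snv_candidates:
        snv_by_family.setdefault(cand.family_id, []).append(cand)

    details = []
    for t in truth_events:
        hit = False
        if t.scenario in {"de_novo_snv", "inherited_dominant",
                          "homozygous_recessive", "x_linked"}:
            for cand in snv_by_family.get(t.family_id, []):
                if (cand.variant.key == t.key
                        and cand.inheritance == t.expected_inheritance
                        and cand.tier == t.expected_tier):
                    hit = True
        elif t.scenario == "compound_het":
            keys = set(t.key.split("|"))
            found = {cand.variant.key
                     for cand in snv_by_family.get(t.family_id, [])
                     if cand.inheritance == "compound_het"
                     and cand.tier == t.expected_tier}
            hit = keys <= found
        elif t.scenario in {"de_novo_cnv", "homozygous_cnv"}:
            chrom, start, end, cnv_type = _parse_interval_key(t.key)
            for cnv in result.family_cnvs.get(t.family_id, []):
                same_locus = (cnv.chrom == chrom and cnv.type == cnv_type
                              and abs(cnv.start - start) <= 1_000
                              and abs(cnv.end - end) <= 1_000)
                want = ("de_novo" if t.scenario == "de_novo_cnv"
                        else "homozygous")
                if (same_locus and cnv.inheritance == want
                        and cnv.known_label == "known"):
                    hit = True
        elif t.scenario == "tre_known":
            fam = result.pedigree.family(t.family_id)
            fam_ids = set(fam.ids())
            for locus, genes in result.tre_matches:
                if t.gene in genes and locus.carriers & fam_ids:
                    hit = True
        elif t.scenario == "mtdna":
            fam = result.pedigree.family(t.family_id)
            fam_ids = set(fam.ids())
            for h in result.mt_hits:
                if (h.observation.sample_id in fam_ids
                        and h.de_novo_heteroplasmy
                        and f"MT:{h.observation.position}:"
                            f"{h.observation.ref}:{h.observation.alt}" == t.key):
                    hit = True
        details.append({"truth": t, "recovered": hit})

    n_truth = len(details)
    n_hit = sum(1 for d in details if d["recovered"])

    # causal calls outside planted (family, gene) pairs count against
    # specificity
    planted_pairs = {(t.family_id, g)
                     for t in truth_events for g in t.gene.split(",") if g}
    false_calls = [
        cand for cand in result.snv_candidates
        if cand.tier in {"known_panel", "novel_candidate"}
        and (cand.family_id, cand.variant.gene) not in planted_pairs]

    flagged = result.consanguineous_families()
    return {
        "details": details,
        "n_truth": n_truth,
        "n_recovered": n_hit,
        "sensitivity": n_hit / n_truth if n_truth else 1.0,
        "false_snv_candidates": false_calls,
        "consanguinity_flagged": flagged,
        "consanguinity_errors": flagged ^ consang_truth,
    }
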