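# famvarkit

Family-based whole-genome-sequencing variant prioritization for
neurodevelopmental-disorder cohorts, with first-class support for
consanguineous families.

Rare-disease WGS studies of autism spectrum disorder (ASD) ascertain
affected children together with their parents and siblings, then search
each family for a small set of plausibly causal variants across several
classes: de novo and inherited SNVs/indels, homozygous recessive and
X-linked variants, multi-caller copy-number variants (CNVs), tandem
repeat expansions (TREs), and mitochondrial heteroplasmies.  In
populations with high consanguinity the recessive arm of this search
matters far more than in outbred cohorts, so the pipeline also estimates
parental kinship and per-sample inbreeding to stratify families.
`famvarkit` implements that whole prioritization layer — everything
downstream of variant calling and annotation — as a tested, reusable
Python library with a thin CLI.

## What it computes

**Quality and rarity filtering.** A genotype is analyzable iff the site
is `FILTER=PASS`, genotype quality GQ ≥ 10, depth DP ≥ 20, outside
low-complexity regions, and — for heterozygous calls only — the allele
balance AD_alt/(AD_ref+AD_alt) lies in [0.2, 0.8].  A variant is *rare*
iff its allele frequency is < 1% in **every** configured population
database (1000G, gnomAD, ExAC, a regional reference, an internal DB …).

**Damaging impact.** Loss-of-function consequences (stop gain,
frameshift insertion/deletion, canonical splice site), or *damaging
missense* (Dmiss): at least 5 of 9 in-silico predictors vote
deleterious — CADD ≥ 10, SIFT, PolyPhen2-HDIV/HVAR (probably/possibly
damaging), LRT, MutationAssessor (high/medium), MutationTaster, MPC ≥ 1,
PROVEAN.  A missing predictor never votes.

**Inheritance in pedigrees.** De novo (complete trios only; both
parents hom-ref with passing QC), homozygous recessive (autosomal
hom-alt proband, carrier parents, no unaffected hom-alt sibling),
X-linked recessive (hemizygous male proband outside the PARs, carrier
mother, non-carrier father), inherited dominant (het proband, exactly
one het parent, either multiplex segregation in ≥ 2 affected members or
a dominant-panel gene), and compound heterozygotes phased by parental
transmission (one paternal-only, one maternal-only variant per gene).

**Consanguinity.** The KING-robust kinship estimator

φ̂ = (N_Aa,Aa − 2·N_AA,aa) / (2·min(N_Aa⁽ⁱ⁾, N_Aa⁽ʲ⁾)) + 1/2 −
(N_Aa⁽ⁱ⁾ + N_Aa⁽ʲ⁾) / (4·min(N_Aa⁽ⁱ⁾, N_Aa⁽ʲ⁾))

for parental pairs, and the excess-homozygosity inbreeding coefficient
F = (O_hom − E_hom)/(n − E_hom) per child.  A family is consanguineous
iff parental φ ≥ 0.044 or any child F > 0.1.

**CNVs, TREs, mtDNA.** Per-caller CNV calls are merged single-linkage
within a 500 bp start/end window — first per sample, then across the
cohort — and clusters seen by < 2 callers are dropped; family-aware
rules then label de novo (AF < 0.1%), homozygous (biparental deletion,
AF < 1%), or inherited events, and any base-pair overlap with known
ASD/NDD genes/regions separates known from novel CNVs.  TRE loci are
matched against the known TRE-ASD gene list.  Mitochondrial allele
depths are screened against known pathogenic variants at > 2%
heteroplasmy, with de novo status from undetectable maternal
heteroplasmy.

**Tiering and cohort report.** Candidates in a user-supplied gene panel
(with dominant/biallelic/X-linked modes) are *known-panel*; outside the
panel, de novo events with damaging impact and homozygous events with
gnomAD pRec > 0.9 become *novel candidates*, annotated with pLI and
external-cohort recurrence.  The cohort report tallies per-family
yield, inheritance-category and variant-class splits, and tests the
recessive burden in consanguineous vs non-consanguineous families with
a Pearson chi-square (no continuity correction) and a two-sided Fisher
exact test.

**Synthetic cohorts.** `famvarkit.synthetic_cohort` generates pedigrees
(controllable consanguineous fraction built from explicit first-cousin
parental pairs, F = 1/16), Hardy–Weinberg founders, Mendelian
transmission, and planted causal variants of every class with truth
labels — emitting the exact file formats the pipeline reads.

## Worked example

```python
import famvarkit as fk
from famvarkit.pipeline import PipelineInputs, run_pipeline

spec = fk.CohortSpec(n_families=20, n_background_sites=5000, n_x_sites=500,
                     plant_plan={"de_novo_snv": 2, "homozygous_recessive": 1,
                                 "x_linked": 1},
                     n_recessive_in_consanguineous=1, seed=42)
cohort = fk.simulate_cohort(spec)
inputs = PipelineInputs(records=cohort.records, pedigree=cohort.pedigree,
                        panel=cohort.universe.panel,
                        constraints=cohort.universe.constraints,
                        recurrence=cohort.universe.recurrence)
result = run_pipeline(inputs)
print("consanguineous families flagged:",
      sorted(result.consanguineous_families()))
for c in result.snv_candidates:
    print(f"{c.family_id}  {c.variant.gene}  {c.variant.key}  "
          f"{c.impact}  {c.inheritance}  {c.tier}  votes={c.dmiss_votes}")
```

prints

```
consanguineous families flagged: ['F002', 'F005', 'F007', 'F010', 'F011', 'F014', 'F015', 'F016', 'F018']
F004  PX0001  chrX:60000000:C:T  Dmiss  x_linked_recessive  known_panel  votes=9
F007  PB0001  chr1:60000000:C:T  LoF  homozygous_recessive  known_panel  votes=0
F019  PD0001  chr1:60010000:C:T  LoF  de_novo  known_panel  votes=0
F020  PD0002  chr1:60020000:C:T  Dmiss  de_novo  known_panel  votes=9
```

— the nine consanguineous families are exactly the ones simulated with
first-cousin parents, and all four planted variants come back with
their true inheritance class and tier (the LoF rows carry 0 predictor
votes because LoF status needs no missense-predictor support).  The
burden test on a 6-of-44 vs 1-of-56 stratification:

```python
from famvarkit.cohort_report import burden_test
burden_test([[6, 38], [1, 55]])
# BurdenStats(chi2_statistic=5.3155, chi2_p=0.0211, fisher_p=0.0416)
```

A `famvarkit` console script exposes `simulate`, `relatedness`,
`prioritize`, `cnv`, `mtdna`, and `report` subcommands over the same
functions; annotation field names and every threshold are configurable
via `--config` YAML.

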