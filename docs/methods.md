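# Methods

This note documents the models, rules, and numerical choices behind
`famvarkit`, what the synthetic-data generator does and does not
emulate, and the design decisions taken where the written rules left
room.

## Filtering model

The SNV/indel cascade treats every rule as a pure predicate evaluated
per variant and, where genotype metrics are involved, per sample:

* **QC** (per genotype): `FILTER=PASS`, GQ ≥ 10, DP ≥ 20, site outside
  the low-complexity mask, and allele balance in [0.2, 0.8] for
  heterozygous calls.  The balance bounds are inclusive, consistent
  with how the other printed thresholds (GQ ≥, CADD ≥, MPC ≥) are
  stated.  An allele count of 1 on chrX in a male is hemizygous, not
  heterozygous, so the balance rule does not apply to it — the QC stage
  takes an optional pedigree to know sample sexes.  A record is kept
  when any sample passes; the per-sample verdicts travel with the
  record because inheritance rules need them (a site can pass in the
  child and fail in a parent, which blocks a de novo call rather than
  the record).
* **Rarity**: allele frequency strictly below 1% in *every* configured
  database.  A frequency missing from a database is treated as 0
  (absent), matching the use of these databases as frequency screens;
  all other missing annotations stay missing.
* **Impact**: the nine-predictor vote (CADD ≥ 10, SIFT, PPH2-HDIV,
  PPH2-HVAR, LRT, MutationAssessor high/medium, MutationTaster, MPC ≥
  1, PROVEAN) with a floor of 5 for damaging missense.  Missing
  predictors abstain; they never count toward the floor.

Because QC and rarity are independent predicates, their composition is
order-independent, and raising the MAF threshold or lowering the vote
floor can only grow the candidate set — both are asserted as property
tests.

## Inheritance rules

De novo calls are restricted to complete trios and require both parents
hom-ref *with passing QC* at the site; this genotype-based rule stands
in for the multi-caller de novo consensus used upstream of this
package's scope (the parent QC requirements are the specificity
backstop).  Homozygous recessive requires carrier status in each
genotyped parent and no QC-passing unaffected sibling that is hom-alt.
X-linked analysis is restricted to male probands (hemizygous ALT
outside the configurable PARs, GRCh38 PAR1/PAR2 by default, carrier
mother / non-carrier father when genotyped); female X-linked handling
is deferred.  Inherited dominant requires exactly one heterozygous
genotyped parent plus either segregation in ≥ 2 affected members or
membership of the dominant panel, and no carrier unaffected sibling.
Compound heterozygotes are phased purely by parental transmission: only
variants attributable to exactly one parent participate, and every
paternal × maternal combination within a gene is reported.  Labels are
not mutually exclusive before tiering.

Tiering: panel membership is by gene symbol, and the matched panel mode
of inheritance is carried as an annotation rather than a hard gate —
cohorts genuinely contain de novo hits in genes with recessive disease
associations, so gating on MOI would hide them.  Outside the panel only
de novo (any damaging impact) and homozygous (damaging impact *and*
pRec > 0.9) events are eligible for the novel tier; a homozygous
candidate whose gene has no pRec score is excluded and the exclusion
logged, since an unknown constraint cannot satisfy a ">" threshold.
pLI and external-cohort recurrence counts are annotations on novel
candidates, not filters.

## Relatedness estimators

Kinship uses the KING-robust between-family estimator over autosomal
sites non-missing in both samples; whether the within- or
between-family variant was used originally is not stated, so the robust
between-family form — the usual choice for screening parental pairs of
unknown ancestry — is implemented and documented here.  Inbreeding is
the method-of-moments excess-homozygosity estimator with expected
homozygosity from allele frequencies computed on pedigree founders only
(children duplicate parental alleles and would bias the frequencies).
No small-sample correction factor is applied to E_hom (plink applies
one); at the simulated cohort sizes the difference is far below the
±0.02 tolerance used in the tests.  The X chromosome is excluded from
both estimators, which assume diploidy.  A family is consanguineous iff
parental φ ≥ 0.044 (inclusive) or any child's F > 0.1 (exclusive);
single-parent families skip the kinship criterion but keep the F
criterion, and both criteria are logged separately per family.

## CNV consensus

Merging is transitive single-linkage under the rule "same type, start
coordinates within 500 bp AND end coordinates within 500 bp", applied
per sample first and then across samples; chains are merged because the
published merging tools behave as single-linkage clusterers.  The
≥ 2-caller floor is applied to the per-sample clusters (merge first,
then count distinct callers), since caller agreement is only defined
once a matching rule exists.  Cluster coordinates are per-endpoint
medians — robust and deterministic.  Reference allele frequencies are
matched at ≥ 50% reciprocal overlap with the same type; an unmatched
CNV counts as absent (AF 0).  Homozygosity of a deletion is declared
from the carrier pattern (proband plus both parents) — with real
callers this would need read-depth evidence, a documented limitation of
working from interval calls alone.

## Mitochondrial screen

Heteroplasmy is the alternate-read fraction of an allele-depth table;
screening is a pure lookup against known pathogenic variant lists with
a strict > 2% threshold.  "Undetectable" maternal heteroplasmy is
defined as at or below the threshold (or no alternate reads), a
noise-floor definition rather than a strict zero.  The packaged default
list contains only the three classic variants used in the tests
(m.3243A>G, m.11778G>A, m.14484T>C); full lists are user-supplied TSVs.

## Cohort report

Rows sharing (family, variant class, inheritance) form one *event*, so
two damaging variants on a single homozygous haplotype (neighboring
genes inherited together in a consanguineous proband) are counted
once.  Percentages are rounded to one decimal, half away from zero.
The recessive burden 2×2 (consanguineous vs not × carrying ≥ 1
known-gene homozygous candidate) is tested with both the Pearson
chi-square without continuity correction and the two-sided Fisher exact
test, and both are always reported: on the 6/44-vs-1/56 table the
uncorrected chi-square p (0.021) rounds to the headline 0.02 while the
Fisher p (0.042) does not, so the headline field uses the chi-square
and the Fisher value ships alongside as the conservative alternative.
The report emits exact ratios rather than rounded multiples ("fourfold"
/ "sixfold"-style adverbs are left to prose).

## Synthetic cohort generator

The generator's defaults are the study conditions: 100 families, 44%
consanguineous, 79% complete trios, two multiplex families with three
affected siblings, a 0.846 male proband fraction, and a default plant
plan of 27 known-gene events (9 de novo SNVs, 1 multiplex inherited
dominant, 7 homozygous recessive of which 6 in consanguineous families,
5 X-linked, 1 de novo + 1 homozygous CNV, 2 TREs, 1 mtDNA
heteroplasmy).  Structure choices:

* **Consanguinity** is built explicitly: shared-grandparent founders
  produce two sibs who marry unrelated spouses, and the resulting first
  cousins become the family's parents, so offspring expected inbreeding
  is F = 1/16 and the parental-pair kinship expectation is φ = 1/16.
  The scaffold individuals are simulated for transmission and dropped
  from all outputs.
* **Consanguineous families are always complete trios.**  The kinship
  criterion that detects them requires both parents genotyped; a
  consanguineous family ascertained without a parent would be
  undetectable by construction (cousin offspring have F ≈ 0.0625, below
  the 0.1 F cutoff).  Incomplete trios are therefore drawn from the
  non-consanguineous pool, with the father dropped.
* **Marker density**: 50,000 autosomal background sites with MAF
  uniform on [0.05, 0.5].  At that density the KING-robust φ of a
  simulated first-cousin pair has a standard deviation of roughly
  0.003–0.004 around ≈ 0.061, putting the 0.044 cutoff about five
  standard deviations away — consanguinity flags are then stable across
  seeds.  This is a realistic pruned-marker count for kinship
  estimation.  2,000 X sites are simulated with proper hemizygous male
  transmission (fathers pass their single X to daughters).
* **Genotype metrics**: depths Poisson(40), GQ uniform 60–99,
  heterozygous alt depths Binomial(DP, 0.5); planted sites get fixed
  clean metrics (GQ 99, DP 40, balanced or full-alt AD) so that, at
  zero noise, every planted variant passes QC by construction.
  Background sites carry population AFs equal to their simulation MAF
  (≥ 5%, so the rarity filter removes them deterministically); planted
  variants carry no AF entries (absent from every database).
* **CNV noise**: each plant is emitted by 3 of the 6 simulated callers
  with uniform start/end jitter (default ±100 bp, tested to ±250 bp);
  false positives are caller-specific singleton calls drawn in disjoint
  per-caller coordinate lanes, a model of caller-specific systematic
  artifacts which guarantees no two callers corroborate an artifact.
* **One pseudo-autosome + one X**: genome-scale realism (many
  chromosomes, LD, realistic site-frequency spectra, read-level data)
  is deliberately out of scope — the rules under test are per-site and
  per-interval, so passing tests demonstrate rule correctness and
  estimator calibration, not robustness to alignment artifacts,
  annotation errors, or LD structure in real data.

The fixed plant plan makes the synthetic cohort's summary reproduce the
published stratification (27 known-panel families; recessive burden
6/44 vs 1/56, chi-square p rounding to 0.02) while the truth table
supports exact sensitivity/specificity accounting.

## Numerical choices and degenerate inputs

Positions are 1-based internally (VCF convention); BED inputs are
0-based half-open and converted on read.  Multiallelic sites are split
before any filtering, with the split allele's AD taken as (ref depth,
that ALT's depth).  INFO floats round-trip at float32 precision through
the VCF layer.  Kinship estimates from fewer than 1,000 shared sites
are flagged unusable and excluded from family classification; the
inbreeding coefficient raises on all-monomorphic input (undefined
denominator).  Zero-depth genotypes fail QC with a counted warning.
Zero-margin burden tables report the chi-square as undefined while
Fisher is still computed.  Empty candidate lists yield all-zero
summaries without division by zero.

## Testing strategy

Every operation with a stated example is pinned to that example;
derived expectations come from independent oracles implemented in the
test suite — brute-force interval containment, explicit adjacency + BFS
transitive closure for CNV clustering, exhaustive pair enumeration for
compound heterozygotes, a plain per-call re-derivation of the whole SNV
cascade for 5-family random cohorts, exhaustive hypergeometric
enumeration for Fisher p-values (all 2×2 tables with N ≤ 15, plus
random tables to N = 30), and binomial/pedigree expectations for the
simulators.  The acceptance layer runs the full pipeline on a
100-family synthetic cohort through the actual file formats and
requires 100% planted-variant recovery with correct classes and tiers,
zero background promotions, and exact consanguinity flags.
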