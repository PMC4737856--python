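# Methods

## Specificity scoring and gene classification

The specificity measure (SPM) is the cosine between a gene's
expression vector across tissues and the target-tissue axis,
`x_testis / ||x||₂`. This form has the three properties the
classification relies on: it is bounded in [0, 1], reaches 1 exactly
for exclusive expression, and is invariant to global rescaling (so
FPKM-scale differences between panels do not matter). An all-zero
vector is assigned SPM 0 — an unexpressed gene is treated as
non-specific rather than undefined. The formula sits behind a single
function (`specificity.compute_spm`) so an alternative specificity
index (tau, TSI) could be swapped in without touching the classifier.

Classification uses three independent normal panels plus a
transcript-level panel for the reference data set. All threshold
comparisons are strict exactly as written (`> 0.9`, `≤ 0.9`); where
a boundary value therefore changes the category, the tests pin the
strict behaviour. A gene missing a required SPM is classified
`indeterminate`, never silently defaulted. The identical-sequence-copy
flag used by the C1 rescue rule is an input column: deciding sequence
identity is an upstream alignment concern, not something this package
recomputes from expression.

Protein classes come from peptide evidence only. Protein-level
abundance is the per-tissue sum of the protein's *unique* peptides;
proteins without unique peptides can still show testis-restricted
evidence through shared peptides and get their own class
(`testis_specific_peptide`) rather than being forced into TSP or
non-TSP — this is what rescues multi-copy gene families whose peptides
are never unique.

## Reactivation calling

Expression in a tumour sample is `count > 5` (strict) on the
normalized-read-count scale; "at least 1%" fractions are `≥ 0.01`.

The extreme-expression (EE) rule flags a sample when its count exceeds
`max(floor, Q3 + k·IQR)` over the full cohort vector, defaults
`floor = 32`, `k = 3`. Rationale: CT genes are mostly silent in
tumours, so for the typical gene Q3 and IQR collapse to ~0 and the rule
reduces to a plain high-count cutoff (the floor, chosen well above the
expression cutoff 5); for genes with a real expression baseline the
robust quartile term takes over and the rule becomes scale-robust.
Quartiles use linear interpolation (type 7); at small cohort sizes the
IQR depends on the convention, so it is fixed and recorded in every
output row together with both parameters. Raising `k` can only remove
EE flags (monotonicity is tested).

The status chain is CT ⇐ EECTG ⇐ EECTP: category C1 and ≥ 1%
expressed; plus ≥ 1% EE; plus protein class TSP. CT-ncRNAs are the
same construction on the non-coding side (C2/C4, ≥ 1% expressed).

## Statistics

* Fisher's exact test: the two-sided p sums hypergeometric
  probabilities of tables (fixed margins) no larger than the observed
  table's probability. Probability "ties" are grouped with a relative
  tolerance of 1e-7, which is part of the definition here: distinct
  pmf values at moderate table totals can be closer than double
  rounding error. The test suite verifies every table with N ≤ 40
  against exact rational-arithmetic enumeration.
* Wilcoxon rank-sum: exact by full label enumeration for combined
  n ≤ 12 (ties handled through average ranks), otherwise the normal
  approximation with tie correction and no continuity correction.
* Spearman correlation: average ranks for ties; exact permutation p
  for n ≤ 7, t-approximation otherwise. Constant vectors are returned
  as not-testable (NaN rho, p = 1) rather than raising mid-pipeline.
* Linear fits are OLS with cancer-type indicator covariates; a
  constant response returns slope 0 with p = 1 (undefined slope
  variance), and rank-deficient designs raise. BH adjustment is
  applied within one family per test type per cancer type. Note that
  BH-adjusted values are *not* idempotent under re-adjustment at an
  arbitrary threshold; the property the suite checks is the correct
  one, agreement of `q ≤ α` with the classic step-up rejection set.

## Genomic intervals

Internally every coordinate is 0-based half-open; GTF (1-based closed)
and BED/SEG (0-based half-open) are converted at the readers/writers
only, verified by a 1-bp-feature fixture. Element assignment windows
are strand-aware: promoter-like kinds default to [TSS − 1000,
TSS + 100) in transcription direction; distal kinds (ncRNA, enhancer)
use gene body ± 100 kb. The "−100 to 1 kb" phrasing common for
promoter-proximal elements is ambiguous; this package reads it as 1 kb
upstream to 100 bp downstream and makes both extents configurable per
kind. No enhancer-specific window is established in the literature we
follow; the 100 kb default is a configuration value, not a claim.

The enrichment ratio is the ratio of proportions — fraction of target
genes with ≥ 1 assigned element over the same fraction in background —
so ER = 1 means no enrichment; Fisher supplies the p-value and a
log-ratio normal approximation the 95% CI. The default background is
the C6b coding genes (confidently non-testis-specific). An odds-ratio
variant would be a one-line change but is not the default because the
proportion ratio is what the ER=1 null semantics describe.

CT-coding/CT-ncRNA pairing uses the nearest-edge gap between gene
bodies, strictly below 100 kb, distance 0 for any overlap. A TSS–TSS
distance is the obvious alternative; the gap convention is configurable.

## Copy-number scoring

Focal burden is the summed length of segments with Seg.CN strictly
above +0.2 or strictly below −0.2; boundary values are excluded (the
conservative reading of a cutoff "set to ±0.2"). Allele-specific
segments (nA ≥ nB) are classified at ploidy 2 as: normal (1,1); CnLOH
(total = ploidy, nB = 0); AiCNA (unbalanced otherwise); AbCNA
(balanced aberration), with homozygous deletion (0,0) falling into
AbCNA by the rule and flagged explicitly. The per-sample scores are
genome-length fractions of each class; this makes S_Ai = S_AiCNA +
S_CnLOH hold identically and the scores invariant to splitting
segments — an event-count normalization would have neither property.
Uncovered genome counts as normal. Sex chromosomes are not treated
specially; the synthetic karyotype has no sex chromosomes, and real
input should be pre-filtered to autosomes if desired.

## The synthetic-data generator

The generator emulates the statistical structure of the study design:
three normal-tissue panels of different sizes (27, 16 and 5 tissues,
each containing a `testis` column), a 16-tissue proteome peptide
table, and a tumour cohort with expression, MAF-like mutations,
promoter beta values and both segment tables. One RNG stream per
output table is split from the master seed by a fixed key, so
regenerating one table never perturbs another, and identical
(config, seed) reproduces every file byte for byte.

Planted structure and the default study conditions:

* **TSGs** (default 60 of 1000 genes): testis expression lognormal
  around 50 FPKM (dispersion 0.5); other tissues receive |N(0, 1)|
  leak noise (`leak_level`, 0 = noiseless). Background genes draw a
  lognormal baseline around 20 FPKM shared across tissues, giving SPM
  near 1/√n_tissues.
* **C6a genes**: broadly expressed at the gene level but carrying one
  testis-restricted transcript in the transcript panel (the gene-level
  reference panel is the transcript sum, keeping the two levels
  consistent).
* **Reactivated genes** (default 8, coding): activated per sample at
  `ee_frequency` (default 5%) with magnitude uniform in [10×, 100×]
  the EE floor, so calling is unambiguous at default thresholds;
  non-activated samples sit below the expression cutoff. Other planted
  TSGs stay CT-silent in the cohort.
* **Mutation coupling**: each sample gets a target SMG mutation ratio
  r ~ U(0.02, 0.2) realized through passenger (Poisson, mean 40) and
  carrier-SMG mutation counts; per-gene activation probability is
  `(α + β·r)/n_ee` with planted slope β = −5 and α set so the marginal
  per-gene activation frequency equals `ee_frequency`. One designated
  SMG is additionally mutated in 20% of samples drawn by weighted
  sampling that avoids samples where the first planted gene is active
  (`exclusivity_strength` 1 forces zero co-occurrence).
* **Methylation**: activated genes have promoter betas near 0.7
  lowered by `methylation_effect` (default 0.3) in activated samples;
  everything else is N(0.5, 0.1) clipped to [0, 1]. Effect 0 is an
  exact null (betas independent of activation).
* **Copy number**: per chromosome, samples carry ~6 segments; the
  probability that a segment is aberrant (log-ratio) or
  allele-imbalanced rises from 5% to 50% / 30% in samples where the
  designated imbalance-driver gene is active.
* **CT-ncRNA pairs** (default 2): planted non-coding TSGs placed in
  the gene slot adjacent to a reactivated coding gene (gaps are 5–50
  kb, always within the 100 kb pairing window). Coupling is
  dose-dependent rather than gated on the activation flag — the
  co-activated partner tracks the coding gene's expression, the
  repressive partner is squelched by it — because a coupling visible
  only in the ~5% activated samples displaces too few ranks for a
  cohort-wide rank correlation to detect at desk-scale cohort sizes.

What the generator does **not** emulate: read-level sampling noise and
library-size effects (abundances are drawn on the normalized scale
directly), mutation signatures and per-gene mutation rate covariates,
batch effects between panels, tumour purity, correlated gene-gene
expression structure beyond the planted couplings, and realistic
segment-length distributions. Passing recovery tests therefore
demonstrate that the analysis chain is correct and calibrated on data
matching its model assumptions — not that those assumptions hold in
any real cohort.

## Problem sizes used in the checks

The test and acceptance runs use deliberately small universes chosen
to keep every simulation at desk scale while leaving the planted
effects statistically unambiguous: 60–2000 genes, cohorts of 120–1000
samples, 20–100 seeds for recovery rates and 500 seeds for null
calibration. Null calibration of the exclusivity Fisher tests runs at
30% activation frequency: exact-test p-values at very sparse margins
(e.g. 50 EE samples of 1000) are genuinely discrete and conservative,
so uniformity is only the correct expectation once the margins are
dense. The cohort-wide Spearman checks of instability coupling run at
30% activation for the same power reason (a rank correlation cannot
exceed roughly the activated fraction when the signal is confined to
it).

## Known limitations

* The classifier requires complete SPM profiles; there is no
  imputation for genes absent from a panel (they are reported
  indeterminate).
* Mutation ratios drop zero-mutation samples (logged) — listwise
  deletion, not shrinkage.
* `call_cohort` treats genes independently; no shared-sample
  correlation structure enters the per-gene EE thresholds.
* The pipeline's CNA association stage picks its target gene (highest
  EE fraction EECTG) unless configured; with several strong drivers
  the choice is a heuristic.
* Variant classification in MAF input is not filtered by default
  (total mutation burden counts all rows); `nonsilent_only` drops
  Silent variants from ratio and status computations when set.
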