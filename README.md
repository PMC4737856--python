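# ctcaller

Discovery of cancer-testis (CT) genes and candidate epigenetic driver
genes from expression data, with every downstream association analysis
the question entails: regulatory-element enrichment, mutation mutual
exclusivity, promoter methylation, allele-specific copy-number
imbalance, and coupling to nearby testis-specific non-coding RNAs.

CT genes are genes whose normal-tissue expression is confined to the
testis but which are reactivated in tumours. Because their products are
absent from normal somatic tissue, reactivated CT genes are both
candidate drivers acting through epigenetic activation ("epi-drivers")
and attractive therapeutic targets. `ctcaller` implements the full
analysis chain as a tested, reusable library plus a `ct-caller` command
line, and ships a seeded synthetic-data module that emulates the
statistical structure of the real multi-panel study design (several
independent normal-tissue expression panels, a proteome peptide table,
and tumour cohorts with mutations, methylation and copy-number
segments), so the entire pipeline runs and is verifiable without any
external downloads.

## The quantities at the core

**Tissue specificity (SPM).** For a gene with non-negative expression
vector *x* over tissues, the specificity measure for the testis is the
cosine against that tissue's axis:

    SPM = x_testis / sqrt(Σ_t x_t²)

SPM ∈ [0, 1]; it equals 1 exactly when only the testis is expressed and
is invariant to rescaling. Genes are classified from SPM in three
independent normal panels (a large GTEx-style panel, a medium HBM-style
panel, a small NJMU-style panel) plus transcript-level scores:

| category | rule |
|---|---|
| C1 / C2 | coding / non-coding, SPM > 0.9 in all three panels |
| C3 / C4 | coding / non-coding, reference panel plus exactly one other |
| C5 | reference panel only |
| C6a / C6b | not testis-specific at gene level, with / without a testis-specific transcript |

Known CT genes with SPM = 0 in the reference panel (identical-sequence
gene copies defeat unique read alignment) but SPM > 0.9 in both other
panels are rescued into C1. Testis-specific proteins (TSPs) are defined
the same way from unique-peptide evidence; proteins whose only testis
evidence comes through shared peptides form their own class.

**Tumour reactivation.** In a cancer cohort, a gene is *expressed* in a
sample at > 5 normalized read counts and shows *extreme expression*
(EE) above `max(32, Q3 + 3·IQR)` of the cohort vector. Then, per
cancer type:

* **CT gene** — C1 gene expressed in ≥ 1% of samples;
* **EECTG** — CT gene with EE in ≥ 1% of samples;
* **EECTP** — EECTG whose protein is a TSP.

**Association analyses.** The per-sample *activated EECTP count* is
regressed on the SMG *mutation ratio* (share of a sample's somatic
mutations in significantly mutated genes) and on mean EECTP promoter
methylation; per-gene tests use Wilcoxon rank-sums and Fisher exact
exclusivity with Benjamini-Hochberg FDR. Allele-specific copy-number
segments are classified into allele-imbalanced (AiCNA), allele-balanced
(AbCNA) and copy-neutral LOH states; per-sample scores are genome
fractions with S_Ai = S_AiCNA + S_CnLOH. CT-coding genes are paired
with CT-ncRNAs within 100 kb and rank-correlated.

## Worked example

```bash
cat > config.yaml <<'EOF'
seed: 1
outdir: out
simulate:
  n_genes: 300
  cohort_size: 120
EOF
ct-caller run --config config.yaml
```

This simulates a 300-gene universe (60 planted testis-specific genes,
8 of them reactivated in 5% of a 120-sample tumour cohort, promoter
elements planted at 10× enrichment, full exclusivity against a
designated mutated gene) and runs every stage. Selected output:

* `classification.tsv` — 45 C1 and 15 C2 genes: all 60 planted TSGs
  recovered, no false positives;
* `ct_calls.tsv` — 8 CT genes, 8 EECTGs, 8 EECTPs: exactly the planted
  reactivated set;
* `enrichment.tsv` — promoter ER = 13.1 (Fisher p = 8.9e-14) against
  the planted factor 10; ncRNA ER ≈ 1.06 where ±100 kb windows overlap
  many background genes;
* `mut_assoc_cohort.tsv` — activated-EECTP count vs mutation ratio:
  β = −4.42, p = 2.6e-4 (planted slope −5);
* `meth_assoc_cohort.tsv` — β = −17.7, p = 1.9e-28: activated samples
  are hypomethylated at EECTP promoters;
* `ncrna_pairs.tsv` — the co-activated pair at ρ = +0.88 and the
  repressive pair at ρ = −0.77, both FDR ≪ 0.05.

Every threshold, the seed and input checksums are echoed into
`out/manifest.json`; re-running the same configuration reproduces the
output bundle byte for byte.

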