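# hypro

Desk-scale reimplementation of a transcriptomics analysis that asks how the
response to moderate hypoxia intersects with stepwise malignant
transformation. The study system is a four-stage isogenic fibroblast model
(primary → hTERT-immortalized → SV40-transformed → HRAS-metastasizing),
profiled by bulk RNA-seq under atmospheric and moderate-hypoxia (3% O₂)
conditions with duplicate samples per design cell. The package provides every
computational stage of that analysis as a tested library, and a synthetic-data
generator with planted ground truth so each stage can be verified without the
original sequencing data.

## What it computes

1. **Expression processing** — TPM normalization
   (`TPM_g = (c_g/ℓ_g) / Σ_j (c_j/ℓ_j) × 10⁶`), the expressed-gene filter
   (TPM > 1 in ≥ 1 sample), and Spearman-correlation clustering of group
   means on log₂(TPM + 1).
2. **Differential expression** — a negative-binomial exact test for two
   groups of counts: TMM (trimmed mean of M-values) normalization factors,
   NB dispersion by conditional maximum likelihood with empirical-Bayes
   shrinkage, two-sided tail-doubled exact p-values after quantile-adjusting
   counts to a common library size, and Benjamini–Hochberg adjustment. A gene
   is called at adjusted p < 0.01, |log₂FC| > 1, TPM > 1 — giving hypoxia DEG
   sets per stage ("hDEGs") and progression DEG sets per stage transition.
3. **Directional overlap** — intersecting two directional DEG sets and
   classifying shared genes as co-regulated (same sign) or anti-regulated
   (opposite sign), with arc/Venn count tables and paired-log₂FC regressions.
4. **KO profiling** — gene-weighted mean log₂ fold change aggregated over a
   four-level KEGG-Orthology-style hierarchy (category → subcategory →
   pathway → enzyme), preserving absent categories so profiles from
   different contrasts stay structurally comparable.
5. **Survival stratification** — Kaplan–Meier curves, the log-rank test, a
   minimal-p expression-cutpoint scan over the 20th–80th percentiles, and the
   Cox proportional-hazards hazard ratio of high vs low expression
   (HR = exp(β̂), Efron ties). The scan's selected p-value is reported as
   descriptive: the implicit multiple testing makes it anti-conservative.

The synthetic generator plants per-stage hypoxia effects, per-transition
progression effects with a constructed sign-concordance fraction between the
two axes, and step-hazard survival cohorts with a planted cutpoint — so
sensitivity, FDR, co-regulation fractions, cutpoints and hazard ratios can
all be checked against known truth.

## Worked example

The numbered scripts under `analysis/` run the full study on the default
synthetic dataset (2,000 genes, 4 stages × 2 oxygen conditions × 2
replicates), writing tables under `results/`:

```sh
python analysis/01_simulate.py
python analysis/02_qc_correlation.py
python analysis/03_differential_expression.py
python analysis/04_overlap_classification.py
python analysis/05_ko_profile.py
python analysis/06_survival_cutpoint.py
```

Output of `04_overlap_classification.py` (seed 1):

```
primary hypoxia vs primary_to_immortalized: shared 100, co 70% (planted 70%)
immortalized hypoxia vs immortalized_to_transformed: shared 100, co 40% (planted 40%)
transformed hypoxia vs transformed_to_metastasizing: shared 100, co 92% (planted 92%)
```

Each line intersects one stage's hypoxia DEG set with the DEG set of the
following transformation step: all 100 planted shared genes are recovered by
the DE engine and the co-regulated percentage reproduces the constructed
concordance fraction exactly. And from `06_survival_cutpoint.py`:

```
selected cutoff 61.3 (61.4th percentile; planted 62.0)
log-rank p at selection: 1.21e-20 (descriptive, scan-selected)
Cox HR high vs low: 3.623 (planted 3.0)
```

The scan recovers the planted 60th-percentile cutpoint to within ~1
percentile of expression.

The same pipeline is scriptable through a single CLI
(`hypro run-all --outdir OUT --seed 1`, with per-stage subcommands
`simulate | qc-correlate | de | xcompare | ko-profile | survscan`) driven by
an optional YAML config; every run writes a manifest with the seed, a config
hash and a hash over all outputs, and reruns are byte-identical.

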