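# Methods

This note documents the statistical procedures, the synthetic-data model
behind the test suite, the defaults and the numerical choices, and what the
passing tests do and do not establish about real data.

## Study design and data model

The analysis targets a stages × oxygen-conditions × replicates bulk RNA-seq
design: four isogenic stages of malignant transformation (primary,
immortalized, transformed, metastasizing), two oxygen conditions
(atmospheric, moderate hypoxia), two replicates per cell — 16 samples. Two
families of two-group contrasts are tested: within each stage, hypoxia vs
atmospheric (the "hDEG" sets), and between consecutive stages at atmospheric
oxygen (the progression "DEG" sets).

Counts for gene *g* in sample *s* are modelled negative-binomial with mean
`μ_gs = baseline_g × 2^(planted effects) × f_s` and dispersion `φ_g`
(variance `μ + φμ²`). Progression effects accumulate multiplicatively along
the stage axis; a stage's hypoxia effect applies in its hypoxic samples;
genes carrying both effects compose them multiplicatively. Library factors
`f_s` are log-normal (σ = 0.1) so TMM estimation is non-trivial.

## Expression processing

- TPM is computed per sample from counts and gene lengths; columns sum to
  10⁶ by construction. Gene-level input is used directly; transcript-level
  input would be aggregated by summing transcript TPMs.
- The expressed-gene filter keeps genes with TPM > 1 (strict) in at least
  one sample. Filtering does **not** rescale the remaining TPM values: they
  stay as computed on the full matrix, a deliberate contract asserted by
  test (recomputing on the subset would silently change every value).
- The QC summary averages replicates per (stage, condition), takes
  log₂(TPM + 1), and computes pairwise Spearman ρ. The pseudocount only
  guards log₂(0): Spearman is rank-based, so any positive value gives the
  same ρ. Clustering uses average linkage on 1 − ρ (configurable); the
  linkage choice affects only the display order.

## Differential expression

The DE engine is a from-scratch implementation of the classical exact-test
workflow for small replicated count designs:

- **TMM factors.** Per sample against a reference (the sample whose
  upper-quartile count fraction is closest to the mean), M-values (log₂
  ratio) are trimmed 30% two-sided and A-values (average log abundance) 5%
  two-sided; surviving M-values are combined with inverse delta-method
  variance weights; factors are scaled to geometric mean 1. Trimming uses
  ordinal ranks so heavily tied M-values cannot all fall outside the trim
  window. A sample with < 20 usable genes falls back to factor 1 with a
  warning.
- **Dispersion.** The common dispersion maximizes the NB conditional
  likelihood (given group sums) summed over genes, on counts
  quantile-adjusted to the geometric-mean effective library size (two
  refinement rounds). Per-gene dispersions maximize the gene's own
  conditional likelihood plus `prior_df / residual_df` times the average
  profile — weighted-likelihood shrinkage toward the common value, default
  prior weight equivalent to 10 degrees of freedom; an infinite prior
  returns the common value exactly. On a grid of 29 log-spaced dispersions
  with quadratic interpolation at the maximum.
- **Exact test.** Counts are quantile-adjusted to a common library size
  (mid-probability CDF mapping through the fitted NB), group sums are
  compared under the conditional distribution of one sum given the total
  (enumerated from the joint NB probabilities), the observed outcome is
  included in both tails, the smaller tail is doubled and capped at 1. At
  dispersion → 0 the conditional law reduces to
  Binomial(total, n₁/(n₁+n₂)), recovering the binomial exact test. Genes
  with zero total count get p = 1.
- **BH adjustment** is the standard step-up; NaN p-values propagate and are
  excluded from m.
- **Calling rule.** Adjusted p < 0.01, |log₂FC| > 1, and TPM > 1 in at
  least one of the compared samples (all strict; the TPM rule reads "any
  individual sample", with a group-mean mode available). The expression
  filter is applied **before** testing by default, so it also reduces m in
  the BH step; this is configurable. log₂FC is computed from TMM-normalized
  CPM group means with a prior count of 0.5 per group to avoid infinities.

Bit-level replication of any particular external DE tool's numerics is a
non-goal; correctness is established against brute-force oracles (tail
enumeration, quadratic BH loop, plain trimmed means), closed-form limits
(binomial), and planted-truth recovery (sensitivity ≥ 80%, FDR ≤ 10% at
|log₂FC| = 2, dispersion 0.05, duplicate samples).

## Directional overlap

Two called DEG sets are intersected; a shared gene is co-regulated when the
fold-change signs agree, anti-regulated otherwise. Percentages are rounded
half-up to the nearest integer (89.5 → 90), matching integer reporting
conventions; raw fractions are also emitted. Genes called in one set but
not the other are counted in the Venn margins only — there is no soft or
marginal category, since the calling rule is a hard threshold. With fewer
than two shared genes the paired-fold-change regression is omitted.

## Planted overlap construction

For each aligned (stage, transition) pair the generator plants a fixed
number of shared genes and makes exactly `round(co_fraction × n_shared)` of
them sign-concordant — the concordance is constructed, not sampled, so the
classifier's output can be compared to truth without Monte-Carlo slack (up
to one gene of rounding when `co_fraction × n_shared` is not integral).
Default pair fractions (0.70, 0.40, 0.92) emulate the qualitative pattern of
the modelled biology: hypoxia response resembles early transformation,
diverges after viral-oncogene transformation, and re-aligns late. Planted
genes take baseline means at or above the population median: called DEG
sets are by definition conditioned on expression (TPM > 1), so the planted
programs sample the robustly expressed stratum; this also makes the
end-to-end round trip of the constructed fractions a structural property
rather than a seed-dependent one.

## KO profiling

A four-level forest (category → subcategory → pathway → enzyme, enzymes
mapping to ≥ 0 genes) is aggregated bottom-up from *changed* genes (the
called DEGs of a contrast): an enzyme's value is the mean log₂FC of its
changed genes, and every ancestor's value is the mean over all changed
(enzyme, gene) units beneath it — gene-weighted, not pathway-weighted, so
small pathways cannot dominate a category (a pathway-weighted mode is a
config option). A gene annotated to several enzymes counts once per enzyme,
mirroring annotation redundancy. Status: `absent` when a node has no mapped
genes at all (absent categories are preserved in every profile), `no-change`
when mapped genes exist but none changed or the mean is exactly 0, else
`up`/`down`. The circular-layout export gives each node an angular share
proportional to its enzyme count, so shares sum to 1 within each ring.

## Survival stratification

Kaplan–Meier estimation, the log-rank test and Cox proportional-hazards
regression are delegated to lifelines (Efron tie handling; Newton precision
tightened to 1e-9 on the coefficient); the cutpoint scan is implemented
here. Every distinct expression value within the 20th–80th percentile
window is tested as a threshold ("high" = expression strictly above the
cutoff); the cutoff minimizing the log-rank p is selected, ties breaking
toward the median. The hazard ratio is the exponentiated Cox coefficient at
the selected split. On divergence (e.g. complete separation) a ridge-
penalized, bounded refit is reported with an explicit warning and
`converged = False`.

Two caveats are intrinsic to the procedure and documented rather than
corrected: (i) the scan's minimal p is anti-conservative under the null
(multiple testing over the grid), so it is reported as descriptive; (ii) at
n = 500 with a hazard ratio of 3, the semiparametric information limit for
the Cox log-HR is se ≈ 0.10 (risk sets unbalance as the high-hazard group
depletes, so the parametric exponential bound √(1/d₁+1/d₂) ≈ 0.089 is not
attainable), which makes a ±15% recovery band a ~1.5σ criterion — per-seed
recovery probability ≈ 0.87 even under the information-optimal harness
(balanced allocation, light censoring, no horizon). The recovery harness
uses exactly that design with a fixed seed list; the estimator is unbiased
(mean log-HR deviation ≈ −0.007 over 200 seeds) and matches the closed-form
no-ties partial-likelihood maximizer to ~1e-11.

The survival generator draws expression log-normal(μ=4, σ=0.5) — an
FPKM-like scale with median ≈ 55 — and exponential event times with rate
0.03/yr below and 0.09/yr at/above the planted cutoff (true HR 3), default
cutoff at the 60th percentile, independent exponential censoring (0.05/yr)
and an optional administrative horizon (15 y default in the cohort
defaults; the n = 541 default matches the modelled cohort size).

## Problem sizes and runtime

All defaults are desk-scale: 2,000 genes (stand-in for a ~15k expressed-gene
transcriptome), 150 hypoxia + 200 progression planted genes per axis with
100 shared per aligned pair, NB dispersion 0.05, baseline means log-normal
(median 80, σ = 1). A full end-to-end run (simulate → QC → 7 DE contrasts →
overlap → KO → survival scan) takes ~15 s on one CPU; the complete test
suite runs in ~3 minutes.

## What passing tests do and do not show

The generator realizes NB marginal counts with multiplicative effects,
log-normal library sizes, and a step hazard — it does not emulate
transcript-level quantification, batch effects, correlated genes, GC/length
biases, read-level noise, or real censoring mechanisms. Passing recovery
tests therefore demonstrate internal correctness of the estimators and
calling rules under the stated model, not pipeline performance on real
libraries; headline gene counts of any particular real dataset are not
reproduction targets (they depend on the original data and tool-version
numerics). Worked-example arithmetic (overlap percentages from printed
counts) is exact and data-independent.

## Known limitations

- The exact test enumerates the full conditional support per gene; for very
  deep libraries (gene totals ≫ 10⁵) a saddlepoint or normal-tail
  approximation would be preferable.
- Dispersion shrinkage uses a single common profile rather than an
  abundance-dependent trend.
- Multivariable Cox adjustment and corrected (e.g. permutation-based)
  cutpoint p-values are out of scope; the scan reports its selection bias
  instead of fixing it.
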