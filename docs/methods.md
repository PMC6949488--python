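# Methods

## Scores and signature expansion

All scores are arithmetic means of log2 expression over a gene set, so a
score is in log2 expression units and inherits the mean's properties:
adding a constant to a sample's column shifts all of its scores by that
constant, and gene-row order is irrelevant. Input matrices are assumed
log2-scale; a `log2(x+1)` transform is available for raw counts or
fluorescence. Gene symbols are case-normalized to uppercase, duplicate
gene rows are collapsed by their mean (unbiased for mean-based scores),
and missing values are rejected rather than imputed, because silent NA
handling would change the means the whole analysis rests on.

Signature expansion fits, for every gene *g*, the ordinary least squares
model

```
x_g = b0 + b_N * N + b_T * T + b_F * F + e
```

where N, T, F are the three prototype scores used simultaneously as
covariates, so each coefficient is a partial association. Per-coefficient
two-sided t-tests (residual df = n − 4) are BH-adjusted within each axis
across all tested genes (three separate families). Plain OLS with
per-coefficient t-tests is used rather than an empirical-Bayes moderated
fit: at cohort scale (hundreds of samples) variance moderation changes
t-statistics negligibly, and the closed-form fit is exactly testable
against normal equations. Zero-variance genes receive coefficient 0 and
p = 1 rather than an error, since real matrices contain flat rows.

Selection takes genes with adjusted p < `alpha_select` (default 0.5, kept
deliberately permissive and configurable) **and** coefficient >
`min_coef` (default 1.0). The threshold is applied to the signed
coefficient because signatures collect *co-expressed* genes; an
absolute-value option exists but is off by default. A gene qualifying on
several axes goes to the axis with the smallest adjusted p (tie: larger
coefficient, then fixed axis order), so a gene belongs to at most one
signature. Each axis list starts with its prototype genes (retained
unconditionally and counted against the cap), followed by candidates in
ascending adjusted-p order (ties: descending coefficient, then gene
name), truncated at `max_genes` = 50. Every sort key is documented and
deterministic; the module uses no randomness. Cohorts below
`min_samples_expand` = 30 samples are scored with the prototype panels
only, the regime intended for small adenoma series.

## Immune-content normalization

"Normalizing for immune content using PTPRC" is implemented as per-gene
residualization: each gene row is replaced by the residual of its OLS
regression on the centered PTPRC row, plus the gene's original mean, and
the PTPRC row itself becomes its mean. Division or subtraction of PTPRC
were rejected because scores are log-scale means and only residualization
exactly removes the linear dependence of every gene on total
infiltration while preserving location. The operator is idempotent and
its output rows have exactly zero sample correlation with PTPRC. A
constant PTPRC row carries no information and yields the identity with a
warning; constancy is detected via the row's range rather than its
centered sum of squares, which can be a few ulp above zero for an exactly
constant row.

## Stratification and rank tests

Samples are split at the median neutrophil score; each neutrophil stratum
is then split at its own median TGFβ score. The high stratum is strictly
`> median`, so samples exactly at the median go to the low group. The
TGFβ split uses the within-stratum median by default — "subdivided into
two groups" reads most naturally as a split within each stratum — with a
global-median option since the original choice is not recoverable.

Mann–Whitney U uses the statistic U = #{(i,j): a_i > b_j} + ½·ties. For
tie-free inputs with min(n_a, n_b) ≤ 8 the p-value is exact (full
enumeration of the U null distribution); otherwise the normal
approximation with tie and continuity correction is used. Two-sided p is
twice the smaller tail, capped at 1. At the crossover (min(n) = 8) exact
and approximate p differ by at most ~0.01 in simulation. The six pairwise
group comparisons are reported without multiplicity correction by
default, matching how individual rank-test p-values are conventionally
reported for such boxplot panels; a BH option exists.

## Cytokine arrays

Differential presence is defined by the asymmetric fold-change window:
log2FC > 0.6 or < −0.4, strict inequalities, independent of any p-value.
Evidence is quantified by a two-sample t-test with variance moderation:
per-cytokine pooled variances are shrunk toward their across-cytokine
median with prior df `prior_df` = 4, i.e.
`s²* = (d0·s0² + d_g·s²_g)/(d0 + d_g)` with total df d0 + d_g — a
closed-form shrinkage estimator in the spirit of empirical-Bayes
moderated tests, chosen so the statistic remains hand-computable in
tests. Welch's t-test is available as an alternative. BH adjustment runs
across all cytokines. Row z-scores use the sample standard deviation
(n − 1); constant rows are an error naming the cytokine.

With the default design (3 vs 3 replicates, noise sd 0.3, planted shift
+1.5 log2 units among 300 cytokines), the planted cytokines' fold changes
are always flagged by the window, while their BH-adjusted p-values sit
near 0.05: with 4 residual df per cytokine this design has only moderate
power, so adjusted significance of both planted cytokines is
seed-dependent. The packaged tests pin the seed and verify the behavior
at that seed; the acceptance script reports both the window flags and the
adjusted-p hits so the distinction stays visible.

## Synthetic cohorts

The generator is the package's substitute for cohort downloads and
encodes the data structure the analysis assumes. Per-sample latent
abundances N (neutrophil), T (T cell), F (TGFβ-active stroma), and M
(monocyte) are log-normal(0, 1) — positive and right-skewed like cell
fractions. The suppressive mechanism is the interaction coupling

```
T <- T + beta_int * standardize(N * F) + eps,   eps ~ Normal(0, 0.25)
```

with `beta_int` = −1 by default: T-cell abundance is reduced exactly
where neutrophils and TGFβ activity coincide, the minimal mechanism
producing the neutrophil-high/TGFβ-high group as the one with the lowest
T-cell score. The residual sd of 0.25 keeps the coupling the dominant
perturbation while leaving sample-level variation. Total immune content
is I = N + T + M and drives the PTPRC row.

Each gene is `baseline + loading · latent + Normal(0, noise_sd)` with
baseline ~ Normal(7, 1) (a typical log2 bulk-expression level) and
noise sd 0.5. Marker genes load at a fixed 0.75; planted co-expressed
genes load uniformly in [0.8, 1.2]. The prototype score's slope on its
latent equals the mean marker loading, so a planted gene's expected
regression coefficient is loading/0.75 ≈ 1.07–1.6 — that is, planted
genes are planted to *be* co-expressed genes under the coefficient > 1
selection rule, while background genes (loading 0) cannot qualify.
Default dimensions are 1,000 genes × 200 samples with 30 planted genes
per axis. CMS-like labels assign CMS4 to the top TGFβ-latent quartile
(the subtype characterized by prominent TGFβ activation) and CMS1–3
uniformly at random to the rest; an optional non-negative
`tgfb_neutrophil_coupling` lets TGFβ-high samples also carry elevated
neutrophil latent for subtype-comparison scenarios. A single seed governs
all draws through independently spawned sub-streams (latents, gene
parameters, noise, labels).

What the generator does **not** emulate: real platform effects, gene-gene
correlation beyond the latent structure, heavy-tailed or count-based
noise, realistic gene counts, or the marginal distributions of actual
TCGA / microarray cohorts. Passing recovery tests therefore demonstrate
correctness of the pipeline under its own model assumptions, not
performance on real cohorts.

One consequence of PTPRC residualization worth knowing: because total
immune content I contains N, residualizing against PTPRC induces a mild
negative dependence of the T-cell score on neutrophil content even when
`beta_int` = 0. With the coupling disabled, no single group is
systematically lowest, but the two neutrophil-high groups are lowest more
often than chance; with the coupling at −1 the double-high group is
lowest in essentially every cohort.

## Problem sizes and determinism

The test suite and acceptance script run on generated data only:
recovery and latent-tracking checks use ten 1,000 × 200 cohorts; the
four-group pattern uses 100 cohorts per coupling setting; Mann–Whitney
calibration uses 2,000 (tests) or 1,000 (script) replicates of four
30-sample groups; the array simulation uses 300 cytokines at 3 vs 3.
These sizes keep every check well-powered while the whole suite runs in
well under a minute. Pipelines are byte-deterministic given (inputs,
config, seed); the run manifest records wall-clock timestamps and is the
one output file excluded from byte-identity comparisons.

## Known limitations

- The expansion regression treats prototype scores as fixed covariates;
  their estimation noise (small, as they average ≥ 4 genes) is ignored.
- Exact Mann–Whitney is limited to tie-free inputs; heavily tied data
  always takes the corrected normal approximation.
- The moderated array test uses a fixed prior df rather than estimating
  it from the data; with very few cytokines the median pooled variance is
  itself noisy.
- No batch correction, probe mapping, or microarray normalization:
  inputs are assumed preprocessed, gene-level, and log2.
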