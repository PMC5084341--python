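# Methods

## Overview

`ripscore` scores individual tumor expression profiles for inferred
proliferative activity by comparing them against the transcriptional
footprint of silencing a homologous-recombination (HR) gene (*BRCA1* or
*RAD51*) in a non-tumorigenic breast cell line. Knocking down either gene
slows proliferation, so genes downregulated in the knockdown are, to a
first approximation, a proliferation program. A tumor whose baseline
expression *resembles* the knockdown profile (program genes low) is
inferred to proliferate slowly; a tumor anti-correlated with it is inferred
to proliferate quickly. The proliferation score is defined as the negative
of the knockdown-similarity score, so that high score = high proliferation.

## Weight vectors from the knockdown comparison

Replicate profiles (log2 scale) are averaged per condition; the per-gene
log-ratio f_i = knockdown_i − control_i is z-scored
(z_i = (f_i − mean f)/sd f, sample sd with n−1 by default). The z vector
is split by sign into z⁺ (upregulated genes) and z⁻ (downregulated genes).
Each |z_i| is mapped to an upper-tail standard-normal probability
p_i = Φ(−|z_i|) and the weight is

    w_i = min(−log10 p_i, cap) / cap,    cap = 10.

Weights live in [0, 1]; w_i = 1 when −log10 p_i reaches the cap, i.e.
|z| ≥ 6.3613. Positive-z weights populate w⁺, negative-z weights w⁻; a
gene carries weight in at most one direction, and z = 0 gives zero in both.

Choices that were genuinely open, and why they were made this way:

* **Tail sidedness.** One-sided p = Φ(−|z|) is the default because the
  z⁺/z⁻ split already separates directions; a weight should measure the
  strength of regulation *within* its direction. Two-sided
  p = 2Φ(−|z|) is available (`two_sided=True`).
* **Rescaling.** Dividing by the trim cap maps the trimmed range [0, 10]
  linearly onto [0, 1] and keeps weights comparable across experiments;
  dividing by the observed maximum (`rescale="max"`) is offered but makes
  the scale depend on the single most extreme gene.
* **Log base.** log2, the standing convention for expression ratios.
* **Gene harmonization.** Symbols are matched case-insensitively and
  duplicate probes for one symbol are collapsed by mean before any step.

## Tumor matrix preprocessing

One-channel (absolute intensity) matrices are log2-transformed
(offset 1 by default), quantile-normalized across samples (classic
mean-of-order-statistics scheme; ties receive the mean of the reference
values their ranks span), then each gene is centered by its across-sample
median, yielding relative expression. Two-channel (log-ratio) matrices are
already relative and pass through untouched. Quantile normalization and
median centering are both idempotent, which the tests exercise. Genes with
any missing value are dropped from the dataset rather than imputed.

## The modified BASE statistic

For one sample with relative expression e and one weight vector w, genes
are sorted by decreasing e (ties broken by gene id, so results are
deterministic). Along that order two CDF-like running sums are formed:

    h(i) = Σ_{j≤i} w_j / Σ_j w_j          (foreground)
    b(i) = Σ_{j≤i} (1 − w_j) / Σ_j (1 − w_j)   (background)

and the statistic is the signed maximum deviation d = h(i*) − b(i*) at the
first index i* maximizing |h − b|. When high-weight genes concentrate at
the top of the expression ranking, h rises faster than b and d > 0.
The foreground cumulates the weights themselves; a variant that also
weights by expression magnitude is a known alternative for this family of
statistics, but the plain-weight form is the default here because it keeps
the statistic purely rank-based (invariant to any monotone transform of a
sample's values, which the tests assert as shift invariance).

d is normalized against an empirical null built by uniformly shuffling the
weight-to-gene assignment (equivalent to shuffling the sample's ranks):
nonnegative d divides by the mean of the nonnegative null deviations,
negative d by the mean magnitude of the negative ones (falling back to the
mean |null| if the same-sign subset is empty; an all-zero null scores 0
with a warning). The normalizer is a scale factor, not a z-score, so a
score of 1 means "as large as a typical same-sign chance deviation".

Scoring both weight vectors gives score⁺ and score⁻;
similarity = score⁺ − score⁻, and the proliferation score is
−similarity.

Numerical/implementation notes:

* Null permutations default to n_perm = 1000 (minimum 100 enforced).
  Each sample draws its own null; the per-sample seed is derived from the
  master seed plus a CRC32 hash of the sample id, so cohort scores are
  bit-reproducible *and* invariant to column order.
* Inside the null, the column sums of the permuted weights are
  permutation-invariant, so h − b reduces to a single cumulative sum per
  permutation; that accumulation runs in float32 because the null only
  feeds a mean (relative error ~1e-4, far below permutation noise at
  n_perm = 1000). The sample's own statistic is computed in float64 and is
  tested against a brute-force reference at 1e-12.
* Degenerate inputs: an all-equal weight vector yields d = 0 (flagged);
  a constant-expression sample scores 0 with a warning.

## Downstream analyses

* **Stratification.** By sign (score < 0 vs > 0; exact zeros join the low
  group with a warning) or by empirical tertiles (cuts at the 1/3 and 2/3
  quantiles, ties to the lower group).
* **Classification.** AUC via the Mann–Whitney rank formulation, ties
  counting 1/2 (cross-checked against scikit-learn in the tests).
* **Survival.** Kaplan–Meier curves and the across-group log-rank test,
  and multivariate Cox proportional-hazards fits, both delegated to
  lifelines; the Cox coefficients are cross-checked against an independent
  partial-likelihood optimization in the tests. Output schema:
  coefficient, Wald p, hazard ratio, 95% CI.
* **Chemoresponse.** Per-group pathologic-complete-response rates and the
  high/low fold ratio; random-forest pCR classifiers (scikit-learn,
  200 trees) with and without the score among the clinical features,
  evaluated by 10-fold cross-validation repeated 10 times.
* **Contingency folds.** Ratio of two event frequencies with a 2×2
  chi-square (no continuity correction by default; Yates by flag).
* **Genome instability.** Per-sample copy-number deviation
  CND = Σ|log2(c_i/2)·f_i| / N over abnormal segments (c_i copy number,
  f_i = end − start + 1 with 1-based inclusive coordinates, N genome size,
  default 3,095,677,412 = GRCh37 total); a `log2ratio` dialect treats the
  segment value as log2(c/2) directly. Mutated-gene counts are distinct
  genes per sample with at least one non-synonymous or indel variant
  (MAF classes: Missense/Nonsense/Nonstop, Translation_Start_Site,
  Splice_Site, Frame_Shift_Del/Ins, In_Frame_Del/Ins; configurable set,
  unknown classes warn and are excluded).

## Synthetic study design

The generator produces every input the pipeline reads, with known truth,
so each stage is testable end to end without external downloads.

* **Knockdown experiment.** Per-gene baselines ~ N(8, 2) on log2 scale;
  3 control + 3 knockdown replicates with N(0, σ_e = 0.7) noise; module
  effects δ_g = −|N(1.5, 0.5)| for the 300 down-module (proliferation
  program) genes, +|N(1.5, 0.5)| for the 150 up-module genes, 0 for the
  remaining ~4550 genes. A designated *MKI67*-like marker sits in the
  down-module. Under these defaults about 80% of module genes land in the
  top-|z| 2m list after standardization — weak-effect draws plus replicate
  noise account for the rest, which is intended: the weighting scheme, not
  a hard gene list, carries the signal.
* **Tumor cohort.** Latent activity a_s ~ N(0, 1); the 15% hereditary
  samples are shifted by +1.0 (modeled as an activity shift because
  hereditary tumors score as more proliferative, not as literal copies of
  the knockdown). Expression e_{g,s} = β_g·a_s + N(0, 0.7) with
  β_g = −κ·δ_g and κ = 1.0, so down-in-knockdown genes rise with
  proliferation. The matrix is emitted as two-channel (already relative).
* **Clinical.** Event times exponential with hazard 0.02·exp(0.8·a_s)
  per month (≈ 35-month median at a = 0); censoring is independent
  Uniform(0, C) with C solved numerically so the expected censored
  fraction equals the configured 0.4. Exponential + uniform censoring was
  chosen for closed-form sanity checks. pCR ~
  Bernoulli(logistic(−2.5 + 1.2·a_s)). Covariates (age, ER/PR/HER2,
  size, stage, grade, nodes) carry mild correlation with activity.
* **Instability.** Mutated-gene counts ~ Poisson(exp(log 20 + 0.5·a_s))
  over a 2000-gene universe, plus Silent passenger rows that the counter
  must ignore; a TP53-like gene mutates with probability
  logistic(−1.5 + a_s). Copy-number segments live on a toy genome of five
  40-Mb chromosomes; segment counts ~ Poisson(exp(1 + 0.5·a_s)) and
  high-level (c = 4) events become more likely with activity.
* **Null switches.** κ = 0, γ = 0, pcr_slope = 0 and mut_c1 = 0 decouple
  the respective layer from activity; the tests use them as false-positive
  controls.

What the generator does **not** emulate: probe-level microarray noise,
batch structure, cross-platform effects, gene–gene correlation beyond the
single latent factor, subtype structure, or methylation. Passing tests
therefore demonstrate that the pipeline recovers a planted one-factor
proliferation signal under realistic noise — not that it reproduces any
particular published cohort value, which would require the original data.

## Problem sizes used in the checks

The default synthetic study is 5000 genes × 500 samples with
1000-permutation nulls — large enough that the truth-recovery metrics
(activity correlation ≥ 0.8, quartile-separation AUC ≥ 0.9, sign-stratified
log-rank p < 0.01, strictly increasing pCR tertile rates, null-calibration
|mean score| < 0.1) are stable to the choice of seed. Unit tests run on
reduced instances (≤ 2000 genes, ≤ 120 samples) chosen to keep the default
suite quick while preserving the properties under test.

## Known limitations

* The permutation null is drawn per sample. Deviations under the null do
  not depend on the sample's values, so a shared null would be cheaper;
  per-sample draws were kept because they make each sample's score
  self-contained and independent of cohort composition.
* The normalizer (mean same-sign null deviation) is one of several
  reasonable choices (sd-based z-scores being the obvious alternative);
  scores should be compared within, not across, normalizer conventions.
* Cox and random-forest steps inherit the assumptions of their libraries
  (proportional hazards; default tree hyperparameters).
* CND treats all abnormal segments equally regardless of chromosome and
  assumes segment calls are non-overlapping; overlapping input segments
  are summed as given.
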