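# ripscore

Single-sample scoring of breast-tumor expression profiles for inferred
proliferative activity, using the transcriptional footprint of RNAi
knockdown of a homologous-recombination gene (*BRCA1* or *RAD51*) as the
reference signature, together with the downstream cohort analyses that
such a score supports: hereditary-vs-sporadic discrimination, survival
association, neoadjuvant-chemoresponse prediction and genome-instability
correlation. A synthetic study generator with known ground truth stands in
for the original microarray/sequencing cohorts, so the entire pipeline is
exercisable and testable offline.

Intended users: computational biologists who want a transparent,
reproducible implementation of knockdown-signature scoring for expression
cohorts, or a harness for studying how such scores behave under a
controlled generative model.

## The method

**Weights.** Replicate knockdown and control profiles (log2) are averaged
and compared per gene: f_i = knockdown_i − control_i, z-scored to
z_i. Each |z_i| maps to a standard-normal upper-tail probability p_i and a
weight w_i = min(−log10 p_i, 10)/10 ∈ [0, 1]. Positive-z genes populate
w⁺, negative-z genes w⁻.

**Scoring.** For each tumor sample, genes are sorted by decreasing
relative expression (one-channel matrices are first log2-transformed,
quantile-normalized and median-centered; two-channel matrices are already
relative). Along the sorted order two CDF-like running sums accumulate:
h(i) ∝ Σ_{j≤i} w_j and b(i) ∝ Σ_{j≤i} (1 − w_j), both ending at 1. The
signed maximum deviation d = h(i\*) − b(i\*) is normalized against an
empirical null obtained by shuffling the weight-to-gene assignment
(1000 permutations per sample, per-sample seeds derived from one master
seed), giving score⁺ and score⁻. Then

    similarity = score⁺ − score⁻        (resemblance to the knockdown)
    RIPS       = −similarity            (inferred proliferation)

Since silencing *BRCA1*/*RAD51* arrests growth, tumors *resembling* the
knockdown are inferred to proliferate slowly; high RIPS means high
proliferation.

**Downstream.** Sign and tertile stratification; Mann–Whitney-rank AUC;
Kaplan–Meier/log-rank and multivariate Cox (via lifelines); per-group pCR
rates and fold ratios; 2×2 contingency folds with chi-square; per-sample
copy-number deviation CND = Σ|log2(c_i/2)·f_i|/N and non-synonymous
mutated-gene counts; random-forest pCR classifiers with/without the score
(10-fold CV × 10 repeats, scikit-learn).

See `docs/methods.md` for assumptions, parameter defaults and limitations.

## Worked example

The numbered scripts under `analysis/` run the whole study on the
synthetic cohort (seed 17; outputs land in `results/`):

```bash
python analysis/01_simulate_cohort.py        # cohort + knockdown experiment
python analysis/02_derive_weights.py         # weight vectors
python analysis/03_score_cohort.py           # RIPS per sample (~3 min)
python analysis/04_stratification_survival.py
python analysis/05_chemoresponse.py
python analysis/06_genome_instability.py
```

Output of a complete run:

```
simulated 500 tumors x 5000 genes (450 module genes, 77 hereditary); wrote 7 tables to results/cohort/
weights for 5000 genes: 2571 up, 2429 down, 0 at the trim cap
top-300 up/down gene lists -> results/top300_genes.tsv
scored 500 samples -> results/scores.tsv
corr(proliferation score, latent activity) = 0.947
corr(proliferation score, MKI67 expression) = 0.874
hereditary-vs-sporadic AUC by proliferation score: 0.806 (77 hereditary of 500)
sign-stratified log-rank: chi2 = 93.00, p = 5.22e-22 (low n=208, high n=292)
Cox (multivariate): score HR = 1.046 [1.033, 1.059], p = 4.37e-12
pCR rate, low tertile: 4.8% (8/167)
pCR rate, intermediate tertile: 10.8% (18/166)
pCR rate, high tertile: 32.9% (55/167)
high/low pCR fold: 6.87
RF pCR AUC (clinical + score): 0.697 (sd 0.009)
RF pCR AUC (clinical only): 0.626 (sd 0.010)
Spearman corr(score, mutated-gene count) = 0.921
median CND by score tertile: low=0.0135, intermediate=0.0306, high=0.0630
synthetic TP53 mutation: 28/208 score-negative vs 118/292 score-positive; fold 3.00, chi2 p = 6.47e-11
published TP53 counts 25/478 vs 74/342: fold 4.14 (rounds to 4.1), chi2 p = 1e-12
published pCR rates 5.8% vs 36.9%: fold 6.36 (rounds to 6.4)
```

Reading it: the score recovers the latent proliferation activity the
cohort was generated from (r = 0.947) and tracks the *MKI67*-like marker
gene; score-positive tumors relapse earlier (log-rank p ≈ 5e-22) and the
score stays prognostic after adjusting for clinical covariates; the pCR
rate climbs nearly seven-fold from the low to the high score tertile and
adding the score to the clinical random forest lifts the pCR AUC from
0.63 to 0.70; mutation burden, copy-number deviation and TP53-like
mutation frequency all rise with the score. The last two lines recompute
the published worked examples directly from their printed counts.

A `ripscore` console command exposes the same steps for arbitrary TSV
inputs (`ripscore weights / preprocess / score / simulate / stratify /
survival / classify / instability / pcr`); run `ripscore --help`.

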