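# Methods

This note records the statistical models implemented in `epidrug`, the
defaults and why they were chosen, what the synthetic generators do and do
not emulate, and the numerical conventions. Nothing here states an empirical
result that the test suite or `scripts/acceptance.py` does not itself
compute.

## Differential calling

Beta values are methylated-signal fractions in [0,1], aggregated per gene as
the arithmetic mean of all probes annotated to one region (TSS200, TSS1500,
gene body by default; 5'UTR, 3'UTR and 1stExon are accepted labels). A probe
annotated to several genes contributes to each of them; exact duplicate
(probe, gene, region) rows collapse.

The per-row two-group test is a **Welch t-test** (unequal variances). An
empirical-Bayes moderated test would shrink row variances, but at the sample
sizes this pipeline targets (tens per arm) the moderation changes little and
the Welch statistic is assumption-light and directly checkable against
first-principles oracles. p-values are Benjamini–Hochberg adjusted per
region (methylation) or per matrix (expression). Rows constant in both
groups get p = 1 rather than NaN so the BH input stays well defined.

Thresholds: FDR < 0.01 with Δβ > 0.1 (Hyper) or Δβ < −0.1 (Hypo); FDR < 0.01
with log2FC > 2 (Up) or < −2 (Down). Δβ and log2FC are oriented tumor −
normal throughout. Expression is assumed to arrive already on the log2
scale, so log2FC is a plain difference of group means.

Batch adjustment is a per-gene location–scale standardization (each batch
shifted/rescaled to the pooled mean and SD). It removes additive and
multiplicative batch offsets exactly; it is *not* an empirical-Bayes method
and does not pool information across genes, which is acceptable here because
the generator's batch effects are exactly location–scale.

## DMEG grouping

A DMEG is a gene significant in both a methylation region and expression,
grouped by the two signs. When a gene carries conflicting methylation calls
across regions (Hyper in one, Hypo in another), the union keeps the region
with the larger |Δβ| and logs the conflict; some tie-break is required for a
one-row-per-gene union and the magnitude rule is the least arbitrary.
Over-representation uses the upper-tail hypergeometric test against
user-supplied GMT collections; the default universe is the set of measured
genes (the measured background), not the genome.

## Diagnostic classifier

Features are z-scaled per column on training statistics (which also puts
the methylation and expression blocks on one scale), projected by PCA
fitted on training data only, and classified by a Fisher linear
discriminant on the component scores. The retained component count defaults
to the smallest number explaining ≥ 90 % of training variance — the
construction is under-specified in the source workflow, so the variance
target is exposed as a parameter. ROC/AUC uses the trapezoidal curve, which
equals the tie-corrected Mann–Whitney concordance.

## Network proximity screen

The weighted closest distance and its permutation z-score are implemented
exactly as defined in the README. Conventions that required a decision:

- **D in ω = −ln(D+1)** is the degree of the target node itself; this is
  the only reading that makes ω well defined per summand.
- Random reference sets **match the target-set size only** (uniform node
  sampling without replacement). A degree-binned sampler (log2 degree bins)
  is available behind `degree_binned=True` but off by default.
- Targets absent from the graph or unreachable from S are **dropped** and
  counted in `n_targets_used`; an infinite distance would otherwise dominate
  the mean. A drug with no usable target is excluded from ranking.
- The empirical p uses the add-one estimator (1 + #{null ≤ d_obs})/(n_perm+1),
  so p > 0 always. With hop-count distances the null is heavily tied, which
  makes this estimator *conservative*: P(p ≤ α) ≤ α holds (verified in the
  tests), while the underlying permutation rank with random tie-breaking is
  exactly uniform. Distance windows (e.g. "0 to 3") are not applied as hard
  filters; screening keys on FDR and reports d_obs.
- Only the target side is permuted; the disease set stays fixed.

Permutation nulls are cached per target-set size within one screen, which is
exact because the null depends on the targets only through their count.

## Prognostic signature

- **Lasso flavor:** L1-penalized Cox partial likelihood
  (`CoxnetSurvivalAnalysis`), features standardized, penalty path of 50
  alphas fitted once on the full data. Each of the `n_runs` repetitions
  re-draws the 10-fold assignment, scores the shared path by held-out
  Breslow partial-likelihood deviance, and picks the penalty by the
  **one-standard-error rule** (sparsest penalty within one SE of the CV
  minimum — the conventional `cv.glmnet` choice; `rule="min"` is available).
  Genes nonzero in the full-data path at that penalty are counted.
- **Top-gene rule:** sort frequencies descending, cut at the largest drop
  (no interior drop ⇒ keep all selected), hard cap 3 by default.
- **Stepwise AIC:** bidirectional search from the full candidate set,
  minimizing AIC = 2k − 2·log partial likelihood; ties in the partial
  likelihood are handled by lifelines' Efron approximation (the synthetic
  event times are continuous, so Efron and Breslow coincide there). The
  empty model's AIC uses the null partial likelihood. Non-convergent moves
  are skipped with a warning; a non-convergent initial or final fit raises
  `StepwiseError` naming the subset.
- **Cutpoint:** candidate cutoffs are midpoints between consecutive distinct
  scores; splits leaving a group under `min_group_fraction = 0.1` (the usual
  surv_cutpoint `minprop`) are inadmissible; the split maximizing the
  log-rank statistic wins, smallest cutoff on ties.
- **Known limitation:** the log-rank p at a *maximally selected* cutpoint is
  anti-conservative — the maximization is a multiple look at the data. On
  null cohorts (n = 150) roughly 10 % of refit splits reach nominal
  p < 0.01. This mirrors the behavior of surv_cutpoint-based analyses in
  general; downstream users should treat refit-cutoff p-values as
  descriptive. Validation with frozen coefficients re-derives the cutoff per
  cohort by design.
- **Time-dependent AUC:** IPCW cumulative-case/dynamic-control estimation
  (`cumulative_dynamic_auc`), censoring distribution from the evaluation
  cohort unless a training table is supplied. Horizons with no preceding
  event, or at/beyond the follow-up maximum, are reported as NaN. Under no
  censoring the estimator reduces to the plain binary ROC AUC of
  "event by horizon", which is the correctness oracle used in the tests.

## Synthetic generators

All generators are pure functions of their config (seed included).

- **Methylation:** per (gene, region), a normal-arm mean is drawn uniformly
  (0.2–0.5 for planted hyper genes, 0.5–0.8 for hypo, 0.2–0.8 for nulls) and
  the tumor mean is shifted by ±`delta_beta_effect` (default 0.15; floor 0.1
  to stay at/above the calling threshold). Probe values are
  Beta(μc, (1−μ)c) with concentration c = 50 by default (per-probe SD ≈
  0.05–0.07, a typical clean-array noise level), keeping values in [0,1]
  without clipping; probes get a small shared ±0.03 baseline jitter. Planted
  genes shift in all three analysis regions. Defaults: 100 + 100 samples,
  3 probes per gene-region, 25 planted genes per group.
- **Expression:** baseline per gene uniform on log2 4–10, Gaussian noise
  with SD 0.5 (log-normal on the natural scale); Up/Down groups shift the
  tumor arm by ±`log2fc_effect` (default 3; floor 2).
- **Survival:** exponential inversion with hazard
  `baseline_hazard · exp(Σ β_g (x_g − mean))`; covariates are mean-centered
  so `baseline_hazard` (default 0.15/year) is interpretable at the cohort
  average. `censor_rate = 0` means no censoring at all; otherwise each
  sample independently receives a Uniform(0, `max_followup`) censoring time
  with probability `censor_rate` and the administrative cap `max_followup`
  (10 years) otherwise — independent of covariates by construction.
- **Network:** Barabási–Albert preferential attachment (default 300 nodes,
  m = 3), whose degree heterogeneity is what the −ln(D+1) weight reacts to.
  The disease module is a BFS ball around a random node (connected, like a
  disease neighborhood) unless explicit genes are supplied. Planted
  proximal drugs draw their targets from the disease module itself —
  distance 0, the strongest version of "adjacent to the module" — while
  decoys sample targets uniformly over all nodes.

What the generators do **not** emulate: real 450K probe coordinates and
probe-level artifacts (SNPs, cross-reactivity), count-based expression
noise, informative censoring, clinical covariates, and the true PPI's
community structure. Passing tests therefore demonstrate the statistical
machinery is correct and well calibrated under its own assumptions, not
that the biology of any specific cohort is reproduced.

## Problem sizes used in the checks

The automated checks run at desk scale, chosen so each stage's property is
decidable in seconds-to-minutes on one core: cohorts of 100–300 samples and
53–300 genes, 100 repetitions for selection frequencies, 1,000–10,000
permutations for the drug screen, 20–200 seeds for the recovery and
calibration suites. Production defaults (1,000 Lasso runs, 10,000
permutations) remain the package defaults.
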