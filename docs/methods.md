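# Methods

## Pair features

For an ordered gene pair (A, B) and sample *s*, the feature is
`+1` if `expr(A, s) > expr(B, s)` and `-1` otherwise. Ties are coded `-1`:
the comparison is strict, which keeps the encoding two-valued and
deterministic; ties have measure zero for continuous expression and are
rare even on quantized arrays. Swapping the orientation negates the row
(antisymmetry), and each unordered pair appears once, anchored at the
first gene in sort order.

The feature is a function of within-sample ranks only, so any strictly
increasing per-sample transformation of expression — different per sample,
different per cohort — leaves the pair matrix bit-identical. This is the
mechanism by which the signature transfers across platforms; the test suite
asserts it exactly (not approximately) for affine, power, and logarithmic
distortions.

The pair universe is every (anchor, partner) combination where anchors are
the genes surviving the screening stages and partners default to the whole
expression matrix. Anchor–anchor pairs are included: each prognostic gene is
paired with every other gene, and restricting partners to non-anchors can
silently delete exactly the most informative contrasts when several
prognostic genes participate in the same relative-order signal. Callers may
still pass an explicit partner list.

Pairs coded `+1` in more than 80% or fewer than 20% of training samples are
near-constant and are removed (bounds inclusive: frequencies of exactly
0.20 or 0.80 are retained). This both preserves variability and caps the
leverage any single sample has on a pair's coding.

## Signature construction

Training proceeds in fixed order; each stage logs its feature count and a
stage that returns zero features raises an error naming itself:

1. **Gene screen.** Per candidate gene, a univariate Cox fit and a
   Kaplan–Meier comparison at the gene's maximally selected cutpoint. A
   gene advances when either p-value is below 0.01 (union rule; an
   intersection rule is available).
2. **Gene-level LASSO-Cox.** L1-penalized Cox on the screened genes'
   (standardized) expression; the penalty is chosen by K-fold
   cross-validated partial-likelihood deviance with the one-standard-error
   rule. The active set becomes the anchor genes.
3. **Pairing** of anchors against the partner universe.
4. **Frequency filter** (20–80%, inclusive).
5. **Per-pair univariate Cox** on the ±1 coding, Benjamini–Hochberg
   adjustment across pairs, retention at q < 0.05 by default (q < 0.01 is
   one config field away; the two thresholds are both defensible readings
   of the source procedure and neither is presumed).
6. **Pair-level LASSO-Cox** on the retained ±1 features, again with
   cross-validated deviance and the 1-SE rule by default (`lambda_stage2 =
   "min"` is exposed, since a deviance-minimum rule is the other natural
   choice and the tighter model it yields may be preferred when validation
   cohorts are plentiful). Pair features enter unstandardized: after the
   frequency filter their standard deviations already lie in a narrow band
   (2·√(f(1−f)) for f ∈ [0.2, 0.8]), and fitting on the raw ±1 scale keeps
   the published score formula `Σ coef · pair` directly interpretable.
7. **Risk cutoff.** The maximally selected log-rank cutpoint on the
   training risk scores. The cutoff is part of the model file and is
   applied unchanged to every validation cohort.

Cross-validation folds are stratified by event status and derived from the
run seed, so a seed fixes the entire fit. Provenance (thresholds, lambda
rules, seed, per-stage counts) is embedded in the model file.

### Cross-validated deviance

Fold deviance uses the Verweij–Van Houwelingen construction:
`dev_k(λ) = -2 [ pl_full(β_k(λ)) − pl_train(β_k(λ)) ]`, the contribution of
the held-out fold measured through the full-data partial likelihood. Unlike
scoring the test fold in isolation, this stays well-defined when a fold
contains few events. The partial likelihood here uses the Breslow tie
convention; with continuous survival times (the simulated setting) Breslow
and Efron coincide.

### Maximally selected cutpoints

Candidate thresholds are midpoints between consecutive sorted unique score
values whose split leaves both groups with at least ⌈minprop · n⌉ samples
(minprop = 0.10, the conventional default for this family of tools). The
returned threshold maximizes |O−E|/√V, the standardized two-group log-rank
statistic; ties resolve to the smallest threshold, making the scan
deterministic. The implementation is an exhaustive scan and the test suite
checks it against an independent re-implementation built on the public
log-rank routine.

At the gene-screening stage the KM p-value for the selected cutpoint is,
by default, adjusted for the threshold search with the Miller–Siegmund
improved-Bonferroni approximation for the supremum of the standardized
log-rank process over the admissible quantile range. The unadjusted
chi-square p of the best split is available
(`screen_genes(selection_adjusted=False)`) but is strongly
anti-conservative: empirically, the unadjusted union rule passes about 14%
of null genes at a nominal 0.01, while the adjusted default passes about
2% (the union of two dependent ~1% tests).

## Survival statistics

- **Cox regression** (public `fit_cox`) uses the Efron tie correction and
  reports coefficient, HR, SE, Wald z and p per covariate. Monotone
  likelihood (separation) is detected — a diverging coefficient with an
  unbounded SE — and raised as an explicit error rather than returned as a
  spurious estimate.
- **Mass univariate screening** (`univariate_cox_scan`) runs scalar
  Newton–Raphson for every feature simultaneously via suffix-sum risk-set
  aggregation, fitting thousands of one-covariate models in a few matrix
  operations (Breslow ties). It is verified against the Efron reference on
  tie-free data and against an independent score-equation root-finder.
- **Kaplan–Meier** and the k-sample **log-rank test** wrap standard
  product-limit and chi-square machinery.
- **BH-FDR** is the standard step-up adjustment, capped at 1.

## Evaluation

**Harrell's C** is computed by explicit enumeration: a pair is usable when
the shorter follow-up ended in an event (tied times are not usable), score
ties count 0.5. The standard error is a delete-one jackknife over subjects
with exact incremental recomputation — one estimator valid at every sample
size, rather than an asymptotic formula with a small-sample fallback; for
U-statistics the jackknife variance is a standard, mildly conservative
choice. Harrell's C (not Uno's) is the primary index because it is the
index the downstream meta-analysis pools; its upward bias under heavy
censoring is shared by all models being compared on the same cohort.

**Time-dependent AUC** is the cumulative/dynamic variant with
inverse-probability-of-censoring weights from the Kaplan–Meier censoring
distribution of the evaluation cohort itself. Horizons with no prior event
or nobody at risk afterwards are skipped with a warning.

**Meta-analysis** pools per-cohort (C, SE) pairs with DerSimonian–Laird:
fixed-effect weights give Q, the moment estimator gives τ², and pooling
weights are 1/(SE² + τ²). `compare_models` forbids pairwise-complete
comparisons — within a cohort every model must score the identical sample
set — and excludes from pooling any model missing a cohort.

Staging systems enter C-index comparisons as ordinal scores (ISS 1/2/3,
refined tiers 1/2/3); C is rank-based, so ordinal encoding adds no
assumptions.

## Staging

The six strata are the cross of risk group and ISS; the merge to three
tiers (low = low_1 ∪ low_2, medium = high_1 ∪ low_3, high = high_2 ∪
high_3) is a fixed published mapping, deliberately not re-derived per
dataset — re-estimating the merge from each dataset's KM curves would be a
different (data-adaptive) method with its own selection optimism.
`stratum_logrank_table` reports all pairwise log-rank p-values between the
six strata so users can check whether the fixed merge is consistent with
their data. Samples without ISS are excluded from staging, never imputed.

## Synthetic cohorts

The generator produces the structure the analysis assumes, with defaults
chosen as study conditions and not revisited:

- **Expression**: gene-wise heterogeneous marginals (normal, log-normal,
  gamma; parameters drawn per gene and per cohort), emulating
  platform-specific distributions. Genes carrying the informative pairs are
  drawn from near-matched normal marginals so that P(A > B) stays within
  roughly 0.3–0.7 and informative pairs survive the frequency filter.
- **Truth**: informative pairs occupy disjoint genes (pair *p* uses genes
  2p, 2p+1), so recovery is unambiguous. Default effects alternate in sign
  with magnitudes spanning 0.3–1.0 on the log-hazard scale.
- **Survival**: exponential baseline (0.02 events/month — median OS near
  three years at η = 0, in line with mid-sized MM cohorts),
  inverse-transform sampling under proportional hazards.
- **Censoring**: independent Uniform(0, C), with C solved by root-finding
  so the expected censored fraction hits the target; the default 0.65
  matches the alive fractions (58–78%) reported across large MM expression
  cohorts. Achieved censoring is within ±5 percentage points of target at
  n ≥ 500 (sampling noise only).
- **ISS**: cumulative-logit with cuts at ±log 2 (equal thirds at zero
  association) and latent shift `strength · 2 · (η + Σ|β|)/(2Σ|β|)`. The
  shift is non-negative for every sample and scales with the association
  strength, so the stage distribution is stochastically ordered toward
  stage 3 in the strength parameter — exactly, not just on average — while
  stage remains positively associated with hazard. A mean-centered link
  cannot deliver that ordering at fixed cuts: inflating a centered latent
  grows both tails, so stage 1 and stage 3 rise together.
- **Batch distortions**: per-sample monotone transforms (affine, power,
  log-shift) layered per cohort; cohort *c* perturbs the seed
  deterministically (seed + 7919·c) and reuses the same truth.

What the generator does **not** emulate: count-based RNA-seq noise
(negative binomial, library size), gene–gene correlation beyond the
informative pairs, informative censoring, cohort-specific effect
heterogeneity, and missing clinical covariates. Passing tests therefore
demonstrate that the pipeline recovers the signal it is designed for under
its own assumptions — not that those assumptions hold in any particular
real cohort.

## Problem sizes used in the shipped tests

Oracle-equivalence checks run on exhaustive event patterns at n ≤ 8 and
random instances at n ≤ 70. Calibration checks use 1000 null log-rank
replicates at n = 200 and single null draws at n = 2000 for C and AUC(t).
Recovery runs 10 seeds at 600 training / 400 held-out / 1500 staging
samples, 100 genes, 10 informative pairs with |β| ∈ [0.8, 1.2]; replicated
selection experiments for the penalized path use 15 replicates at n = 400.
These sizes were chosen so the complete suite exercises every claim at
desk scale.

## Known limitations

- The nested pipeline inherits the optimism of any selection-heavy
  procedure; internal cross-validation controls the penalty choice but the
  screening thresholds (p < 0.01, q < 0.05) are fixed conventions.
- The maximally selected cutoff is estimated once on training data;
  its sampling variability is not propagated into validation-cohort
  inference.
- Harrell's C is censoring-dependent; Uno-style IPCW concordance is not
  currently implemented (the AUC(t) routine covers the IPCW use case at
  fixed horizons).
- With heavy censoring and strong effects the simulated follow-up window
  compresses; AUC horizons must be chosen inside the observed range (the
  routine skips inadmissible horizons with a warning).
- The ±1 coding discards within-pair magnitude information by design;
  pairs whose expression difference is near zero are coded as confidently
  as widely separated ones.
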