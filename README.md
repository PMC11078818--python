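# pairstage

Rank-based gene-pair survival signatures and refined ISS staging for
multiple myeloma expression cohorts.

## The problem

Transcriptomic prognostic models for multiple myeloma (MM) are hard to move
between cohorts: microarray intensities and RNA-seq abundances live on
different scales, and batch effects shift raw expression values even within
one platform. `pairstage` implements a signature built not on expression
values but on the *within-sample relative order* of gene pairs: for a pair
(A, B) a sample is coded

```
pair(A|B) = +1  if expr(A) > expr(B)   in that sample
            -1  otherwise
```

Because the coding depends only on comparisons made inside a single sample,
it is exactly invariant under any strictly increasing per-sample
transformation — affine rescaling, log transforms, quantile-preserving
platform drift — so a model trained on one cohort transfers to another
without renormalization.

The fitted signature is a penalized Cox model over selected pairs,

```
RiskScore = Σ_k  coef_k · pair_k ,
```

dichotomized at a maximally selected log-rank cutpoint into high/low risk,
and fused with the International Staging System (ISS) into a three-tier
refined staging: low = {low-risk ISS 1, low-risk ISS 2}, medium =
{high-risk ISS 1, low-risk ISS 3}, high = {high-risk ISS 2, high-risk
ISS 3}.

## What the package does

- **io**: genes x samples expression TSV, clinical CSV/TSV (configurable
  columns, roman-numeral ISS aliases), versioned JSON model files.
- **simulate**: multi-cohort synthetic data with known informative pairs,
  proportional-hazards survival, calibrated censoring, hazard-linked ISS,
  and per-sample monotone batch distortions — every downstream stage is
  testable without external data.
- **pairing**: pair-matrix construction and the 20–80% frequency filter.
- **survstats**: Cox fits (Efron ties), Kaplan–Meier, log-rank, maximally
  selected cutpoints (with Miller–Siegmund selection-adjusted p-values),
  BH-FDR, and the univariate gene screen.
- **model**: the nested pipeline — gene screen → gene-level LASSO-Cox
  (cross-validated deviance, 1-SE rule) → pairing → frequency filter →
  per-pair Cox with FDR retention → pair-level LASSO-Cox → cutpoint.
- **staging**: six risk-by-ISS strata and the fixed three-tier merge.
- **evaluate**: Harrell's C with jackknife SE, IPCW cumulative/dynamic
  AUC(t), DerSimonian–Laird random-effects meta-analysis, multi-model
  cross-cohort comparison.

## Worked example

```python
import numpy as np
import pairstage as ps

cfg = ps.SimulationConfig(
    n_samples=600, n_genes=100, n_informative_pairs=10,
    pair_coefficients=np.linspace(0.8, 1.2, 10)
    * np.where(np.arange(10) % 2 == 0, 1, -1),
    seed=1,
)
train, validation = ps.simulate_cohorts(cfg, 2)

expr, clin, truth = train
model = ps.train_cell_death_model(expr, clin, list(expr.index),
                                  ps.TrainConfig(seed=1))
print(f"signature: {len(model.pairs)} pairs, cutoff {model.risk_cutoff:.3f}")

expr_v, clin_v, _ = validation
risk = ps.compute_risk_scores(model, expr_v)
conc = ps.harrell_cindex(risk["risk_score"], clin_v["os_time"], clin_v["os_event"])
print(f"validation C-index {conc.c_index:.3f} +/- {conc.se:.3f}")

strata, _ = ps.combine_strata(risk["risk_group"], clin_v["iss"])
refined = ps.refine_iss(strata)
lr = ps.logrank_test(refined.to_numpy(),
                     clin_v.loc[refined.index, "os_time"],
                     clin_v.loc[refined.index, "os_event"])
print(f"three-tier log-rank chi2 = {lr.statistic:.1f}, p = {lr.p:.2e}")
```

prints

```
signature: 23 pairs, cutoff 1.452
validation C-index 0.839 +/- 0.012
three-tier log-rank chi2 = 217.9, p = 4.79e-48
```

The signature trained on cohort 0 is applied, cutoff unchanged, to the
independently simulated cohort 1: a validation C-index of 0.84 means that
in 84% of usable patient pairs the higher-scoring patient died earlier, and
the three refined tiers separate overall survival decisively. Time-dependent
AUC at fixed horizons is available via `ps.time_dependent_auc` (this
simulation's follow-up spans about two years, so horizons of 6/12/18 months
are the admissible choices).

The same workflow is scriptable from the shell:

```bash
pairstage simulate --out-dir data --n-cohorts 2 --seed 1
pairstage train --expression data/cohort0_expression.tsv \
    --clinical data/cohort0_clinical.csv --genes genes.txt --out model.json
pairstage score --model model.json --expression data/cohort1_expression.tsv \
    --out risk.tsv
pairstage stage --risk risk.tsv --clinical data/cohort1_clinical.csv --out staged.tsv
pairstage evaluate --risk risk.tsv --clinical data/cohort1_clinical.csv \
    --horizons 6,12,18 --out report.json
```

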