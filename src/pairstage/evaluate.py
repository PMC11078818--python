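"""Model assessment: Harrell's C, time-dependent AUC, and random-effects
meta-analysis of concordance across cohorts.

Harrell's C is computed by explicit enumeration of usable pairs (a pair is
usable when the shorter follow-up ended in an event), with a delete-one
jackknife standard error.  Time-dependent cumulative/dynamic AUC uses
inverse-probability-of-censoring weighting with Kaplan-Meier censoring
weights estimated on the evaluation cohort itself.  Per-cohort C-indices
are pooled with a DerSimonian-Laird random-effects model.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sksurv.metrics import cumulative_dynamic_auc
from sksurv.util import Surv

from .errors import ValidationError
from .survstats import check_survival

__all__ = [
    "ConcordanceResult",
    "harrell_cindex",
    "time_dependent_auc",
    "MetaResult",
    "meta_cindex",
    "compare_models",
]

logger = logging.getLogger(__name__)


@dataclass
class ConcordanceResult:
    """Harrell's concordance index with jackknife SE and 95% CI."""

    c_index: float
    se: float
    ci95: tuple[float, float]
    n_usable_pairs: int


def harrell_cindex(scores, times, events) -> ConcordanceResult:
    """Harrell's C over usable pairs; higher score should mean earlier failure.

    A pair (i, j) with t_i < t_j is usable iff subject i had an event;
    tied-time pairs are not usable.  Score ties contribute 0.5.  The SE is
    a delete-one jackknife over subjects (exact incremental recomputation),
    appropriate for the U-statistic form of C at any sample size.
    """
    t, e = check_survival(times, events)
    s = np.asarray(scores, dtype=float)
    if s.shape != t.shape:
        raise ValidationError("scores must align with survival data")
    n = len(s)
    if n < 2:
        raise ValidationError("need at least two samples")
    earlier = (t[:, None] < t[None, :]) & (e[:, None] == 1)  # i fails first, observed
    conc = (s[:, None] > s[None, :]).astype(float)
    conc[s[:, None] == s[None, :]] = 0.5
    num_mat = conc * earlier
    num = num_mat.sum()
    den = earlier.sum()
    if den == 0:
        raise ValidationError("no usable pairs (check censoring pattern)")
    c = num / den

    # delete-one jackknife: subject i participates as row i and column i
    num_i = num_mat.sum(axis=1) + num_mat.sum(axis=0)
    den_i = earlier.sum(axis=1) + earlier.sum(axis=0)
    keep = den_i < den  # deleting i must leave usable pairs
    loo = (num - num_i[keep]) / (den - den_i[keep])
    m = len(loo)
    if m > 1:
        se = float(np.sqrt((m - 1) / m * ((loo - loo.mean()) ** 2).sum()))
    else:
        se = float("nan")
    ci = (c - 1.959963984540054 * se, c + 1.959963984540054 * se)
    return ConcordanceResult(c_index=float(c), se=se, ci95=ci, n_usable_pairs=int(den))


def time_dependent_auc(scores, times, events, horizons) -> pd.DataFrame:
    """Cumulative/dynamic AUC(t) at the requested horizons.

    Discrimination between subjects failing by t and subjects surviving
    past t, censoring-corrected by inverse-probability-of-censoring
    weights from the Kaplan-Meier censoring distribution of the evaluation
    cohort.  Horizons with no prior events or nobody still at risk are
    skipped with a warning.
    """
    t, e = check_survival(times, events)
    s = np.asarray(scores, dtype=float)
    if s.shape != t.shape:
        raise ValidationError("scores must align with survival data")
    horizons = np.atleast_1d(np.asarray(horizons, dtype=float))
    admissible = []
    for h in horizons:
        has_case = ((t <= h) & (e == 1)).any()
        has_control = (t > h).any()
        if has_case and has_control:
            admissible.append(h)
        else:
            warnings.warn(f"horizon {h} skipped: no events before or no one at risk after",
                          stacklevel=2)
    if not admissible:
        raise ValidationError("no admissible horizon")
    y = Surv.from_arrays(event=e.astype(bool), time=t)
    aucs, _ = cumulative_dynamic_auc(y, y, s, np.asarray(admissible))
    return pd.DataFrame({"horizon": admissible, "auc": np.atleast_1d(aucs)})


@dataclass
class MetaResult:
    """DerSimonian-Laird random-effects pooling of per-study estimates."""

    pooled_c: float
    pooled_se: float
    ci95: tuple[float, float]
    tau2: float
    weights: np.ndarray  # normalized random-effects weights, sum to 1
    q_statistic: float


def meta_cindex(studies) -> MetaResult:
    """Pool per-cohort (c_index, se) pairs with a random-effects model.

    Between-study variance by the DerSimonian-Laird moment estimator:
    tau2 = max(0, (Q - (k-1)) / (sum w - sum w^2 / sum w)) with fixed-effect
    weights w = 1/se^2; pooling weights are 1/(se^2 + tau2).  A single study
    is returned as-is with tau2 = 0.
    """
    studies = list(studies)
    if len(studies) == 0:
        raise ValidationError("need at least one study")
    c = np.array([float(s[0]) for s in studies])
    se = np.array([float(s[1]) for s in studies])
    if (se <= 0).any() or not np.isfinite(se).all():
        raise ValidationError("all study standard errors must be positive and finite")
    k = len(c)
    if k == 1:
        ci = (c[0] - 1.959963984540054 * se[0], c[0] + 1.959963984540054 * se[0])
        return MetaResult(pooled_c=float(c[0]), pooled_se=float(se[0]), ci95=ci,
                          tau2=0.0, weights=np.array([1.0]), q_statistic=0.0)
    w = 1.0 / se**2
    c_fixed = (w * c).sum() / w.sum()
    q = float((w * (c - c_fixed) ** 2).sum())
    denom = w.sum() - (w**2).sum() / w.sum()
    tau2 = max(0.0, (q - (k - 1)) / denom)
    w_star = 1.0 / (se**2 + tau2)
    pooled = float((w_star * c).sum() / w_star.sum())
    pooled_se = float(1.0 / np.sqrt(w_star.sum()))
    ci = (pooled - 1.959963984540054 * pooled_se, pooled + 1.959963984540054 * pooled_se)
    return MetaResult(pooled_c=pooled, pooled_se=pooled_se, ci95=ci, tau2=float(tau2),
                      weights=w_star / w_star.sum(), q_statistic=q)


def compare_models(model_scores: dict, surv_by_cohort: dict):
    """Concordance of several risk models across several cohorts, plus meta.

    Parameters
    ----------
    model_scores
        ``{model_name: {cohort_name: pd.Series of scores indexed by sample}}``.
        Within a cohort every model must score the identical sample set
        (pairwise-complete comparisons are forbidden); a model missing a
        cohort entirely is excluded from the meta-analysis with a report.
    surv_by_cohort
        ``{cohort_name: (times, events)}`` aligned to each cohort's sample
        order, or ``(times, events, sample_ids)``.

    Returns
    -------
    (table, meta, report)
        table: one row per model x cohort with c, se, ci, n_usable;
        meta: {model_name: MetaResult} for models covering every cohort,
        ordered by pooled C (best first); report: exclusions.
    """
    cohorts = list(surv_by_cohort)
    rows = []
    per_model: dict[str, list] = {}
    report = {"excluded_from_meta": []}
    for cohort in cohorts:
        t, e = check_survival(surv_by_cohort[cohort][0], surv_by_cohort[cohort][1])
        indexes = []
        for name, by_cohort in model_scores.items():
            if cohort in by_cohort and isinstance(by_cohort[cohort], pd.Series):
                indexes.append(by_cohort[cohort].index)
        for other in indexes[1:]:
            if not indexes[0].equals(other):
                raise ValidationError(
                    f"models score different sample sets in cohort {cohort!r}; "
                    "identical sample sets are required"
                )
        for name, by_cohort in model_scores.items():
            if cohort not in by_cohort:
                continue
            scores = np.asarray(by_cohort[cohort], dtype=float)
            if len(scores) != len(t):
                raise ValidationError(
                    f"model {name!r} scores {len(scores)} samples in cohort "
                    f"{cohort!r}, expected {len(t)}"
                )
            res = harrell_cindex(scores, t, e)
            rows.append({"model": name, "cohort": cohort, "c_index": res.c_index,
                         "se": res.se, "ci_low": res.ci95[0], "ci_high": res.ci95[1],
                         "n_usable_pairs": res.n_usable_pairs})
            per_model.setdefault(name, []).append((res.c_index, res.se))
    table = pd.DataFrame(rows)
    meta: dict[str, MetaResult] = {}
    for name, studies in per_model.items():
        if len(studies) < len(cohorts):
            report["excluded_from_meta"].append(
                {"model": name, "n_cohorts": len(studies), "n_required": len(cohorts)}
            )
            continue
        meta[name] = meta_cindex(studies)
    meta = dict(sorted(meta.items(), key=lambda kv: -kv[1].pooled_c))
    return table, meta, report
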