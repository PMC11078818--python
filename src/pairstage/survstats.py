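"""Survival-statistics core: Cox fits, Kaplan-Meier, log-rank, maximally
selected cutpoints, BH-FDR, and the univariate gene screen.

Public model fits go through lifelines (Cox partial likelihood with Efron
tie handling, product-limit estimator, multi-group log-rank).  Mass
screening of thousands of candidate features uses an internal vectorized
Newton solver for one-covariate Cox models (Breslow ties) so a whole
feature panel is fitted in a handful of matrix operations.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.exceptions import ConvergenceError
from lifelines.statistics import multivariate_logrank_test
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import ValidationError

__all__ = [
    "check_survival",
    "fit_cox",
    "km_estimate",
    "logrank_test",
    "LogrankResult",
    "Cutpoint",
    "max_selected_cutpoint",
    "bh_fdr",
    "screen_genes",
    "univariate_cox_scan",
]

logger = logging.getLogger(__name__)


def check_survival(times, events) -> tuple[np.ndarray, np.ndarray]:
    """Validate and coerce a (times, events) pair to aligned arrays."""
    t = np.asarray(times, dtype=float)
    e = np.asarray(events)
    if t.shape != e.shape or t.ndim != 1:
        raise ValidationError(f"times {t.shape} and events {e.shape} must be equal-length 1-d")
    if np.isnan(t).any() or (t < 0).any():
        raise ValidationError("follow-up times must be non-negative and non-missing")
    if not np.isin(e, (0, 1)).all():
        raise ValidationError("event indicators must be 0 or 1")
    e = e.astype(int)
    if e.sum() == 0:
        raise ValidationError("at least one observed event is required")
    return t, e


def fit_cox(X, times, events, robust: bool = False) -> pd.DataFrame:
    """Cox proportional-hazards fit (Efron ties) for one or more covariates.

    Parameters
    ----------
    X
        DataFrame (n_samples x p) or 1-d vector of a single covariate.
    times, events
        Right-censored follow-up and event indicators.

    Returns
    -------
    DataFrame indexed by covariate with columns coef, hr, se, z, p.

    Raises
    ------
    ValidationError
        For constant covariates.
    RuntimeError
        When the partial likelihood does not converge (including monotone
        likelihood / separation), reported explicitly rather than returning
        a spurious estimate.
    """
    t, e = check_survival(times, events)
    if isinstance(X, pd.DataFrame):
        Xdf = X.reset_index(drop=True).astype(float)
    else:
        arr = np.asarray(X, dtype=float)
        if arr.ndim == 1:
            arr = arr[:, None]
        Xdf = pd.DataFrame(arr, columns=[f"x{i}" for i in range(arr.shape[1])])
    if len(Xdf) != len(t):
        raise ValidationError("covariates and survival data differ in length")
    const = Xdf.columns[Xdf.nunique() <= 1]
    if len(const):
        raise ValidationError(f"constant covariate(s): {list(const)}")
    df = Xdf.copy()
    df["_time"] = t
    df["_event"] = e
    cph = CoxPHFitter()
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cph.fit(df, duration_col="_time", event_col="_event", robust=robust,
                    fit_options={"precision": 1e-10})
    except ConvergenceError as exc:
        raise RuntimeError(
            f"Cox fit failed to converge (possible separation/monotone likelihood): {exc}"
        ) from exc
    summary = cph.summary
    runaway = (summary["coef"].abs() > 10) & (summary["se(coef)"] > 10)
    if runaway.any():
        raise RuntimeError(
            "separation (monotone likelihood) detected for covariate(s) "
            f"{list(summary.index[runaway])}: coefficient diverges with an "
            "unbounded standard error"
        )
    out = pd.DataFrame(
        {
            "coef": summary["coef"],
            "hr": summary["exp(coef)"],
            "se": summary["se(coef)"],
            "z": summary["z"],
            "p": summary["p"],
        }
    )
    out.index.name = "covariate"
    return out


def km_estimate(times, events) -> pd.Series:
    """Kaplan-Meier product-limit survival curve.

    Returns a right-continuous non-increasing step function as a Series
    S(t) indexed by time, starting at S(0) = 1.  All-censored input is
    permitted (S identically 1).
    """
    t = np.asarray(times, dtype=float)
    e = np.asarray(events).astype(int)
    if t.ndim != 1 or t.shape != e.shape or len(t) < 1:
        raise ValidationError("times/events must be equal-length non-empty 1-d arrays")
    if (t < 0).any() or not np.isin(e, (0, 1)).all():
        raise ValidationError("invalid survival data")
    kmf = KaplanMeierFitter()
    kmf.fit(t, event_observed=e)
    s = kmf.survival_function_["KM_estimate"]
    s.index.name = "time"
    s.name = "S"
    return s


@dataclass
class LogrankResult:
    statistic: float
    p: float
    df: int


def logrank_test(groups, times, events) -> LogrankResult:
    """k-sample log-rank test (chi-square, df = k-1)."""
    t, e = check_survival(times, events)
    g = np.asarray(groups)
    if g.shape != t.shape:
        raise ValidationError("group labels must align with survival data")
    labels, counts = np.unique(g, return_counts=True)
    if len(labels) < 2:
        raise ValidationError("need at least two non-empty groups")
    res = multivariate_logrank_test(t, g, e)
    return LogrankResult(statistic=float(res.test_statistic), p=float(res.p_value),
                         df=len(labels) - 1)


def _two_group_logrank_z(high_mask: np.ndarray, t_sorted, e_sorted, order=None) -> float:
    """Standardized log-rank statistic (O-E)/sqrt(V) for group = high_mask.

    ``t_sorted``/``e_sorted`` are times and events already sorted ascending;
    ``order`` is the sorting permutation used to align ``high_mask``.
    """
    g = high_mask[order] if order is not None else high_mask
    n = len(t_sorted)
    event_idx = np.flatnonzero(e_sorted == 1)
    ut, inv = np.unique(t_sorted[event_idx], return_inverse=True)
    left = np.searchsorted(t_sorted, ut, side="left")
    n_at_risk = n - left
    suffix_g = np.concatenate([np.cumsum(g[::-1])[::-1], [0]])
    n1_at_risk = suffix_g[left]
    d = np.bincount(inv, minlength=len(ut)).astype(float)
    d1 = np.bincount(inv, weights=g[event_idx].astype(float), minlength=len(ut))
    frac = n1_at_risk / n_at_risk
    expected = d * frac
    with np.errstate(divide="ignore", invalid="ignore"):
        var = np.where(
            n_at_risk > 1,
            d * frac * (1 - frac) * (n_at_risk - d) / (n_at_risk - 1),
            0.0,
        )
    v = var.sum()
    if v <= 0:
        return 0.0
    return float((d1 - expected).sum() / np.sqrt(v))


@dataclass
class Cutpoint:
    """Maximally selected survival cutpoint on a continuous score."""

    threshold: float
    statistic: float  # |standardized log-rank| at the threshold
    n_low: int
    n_high: int


def max_selected_cutpoint(score, times, events, minprop: float = 0.10) -> Cutpoint:
    """Threshold maximizing the standardized two-group log-rank statistic.

    Candidate thresholds are the midpoints between consecutive sorted unique
    scores whose induced split leaves both groups with at least
    ceil(minprop * n) samples.  Ties in the maximal statistic resolve to the
    smallest threshold.  Mirrors the maximally-selected-rank-statistics
    cutpoint search used for survival dichotomization.
    """
    t, e = check_survival(times, events)
    s = np.asarray(score, dtype=float)
    if s.shape != t.shape:
        raise ValidationError("score must align with survival data")
    if not (0 < minprop < 0.5):
        raise ValidationError("minprop must lie in (0, 0.5)")
    n = len(s)
    kmin = int(np.ceil(minprop * n))
    uniq = np.unique(s)
    if len(uniq) < 2:
        raise ValidationError("no admissible cutpoint: score is constant")
    mids = (uniq[:-1] + uniq[1:]) / 2.0
    n_low = np.searchsorted(np.sort(s), mids, side="right")
    admissible = (n_low >= kmin) & ((n - n_low) >= kmin)
    if not admissible.any():
        raise ValidationError("no admissible cutpoint under the minprop constraint")
    order = np.argsort(t, kind="stable")
    t_sorted, e_sorted = t[order], e[order]
    best = None
    for thr, nl in zip(mids[admissible], n_low[admissible]):
        z = abs(_two_group_logrank_z(s > thr, t_sorted, e_sorted, order))
        if best is None or z > best[1] + 1e-12:
            best = (thr, z, int(nl))
    thr, z, nl = best
    return Cutpoint(threshold=float(thr), statistic=float(z), n_low=nl, n_high=n - nl)


def maxstat_pvalue(statistic: float, minprop: float = 0.10) -> float:
    """Selection-adjusted p-value for a maximally selected log-rank statistic.

    Improved-Bonferroni approximation (Miller–Siegmund) for the maximum of
    the standardized statistic over cutpoints spanning the score quantile
    range [minprop, 1 - minprop]:

        p ~= phi(b) (b - 1/b) log[ (1-e1)e2 / (e1(1-e2)) ] + 4 phi(b)/b

    with b the observed maximum and (e1, e2) = (minprop, 1 - minprop).  The
    result is clipped to [2*Phi(-b), 1]; accurate for b >~ 1 and equal to 1
    below that, which is the conservative direction.
    """
    b = float(statistic)
    if b <= 1.0:
        return 1.0
    e1, e2 = minprop, 1.0 - minprop
    span = np.log((1 - e1) * e2 / (e1 * (1 - e2)))
    phi = stats.norm.pdf(b)
    p = phi * (b - 1.0 / b) * span + 4.0 * phi / b
    return float(np.clip(p, 2.0 * stats.norm.sf(b), 1.0))


def bh_fdr(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted q-values (capped at 1)."""
    p = np.asarray(pvalues, dtype=float)
    if p.ndim != 1:
        raise ValidationError("p-values must be 1-d")
    if np.isnan(p).any():
        raise ValidationError("NaN p-value")
    if ((p < 0) | (p > 1)).any():
        raise ValidationError("p-values must lie in [0, 1]")
    if len(p) == 0:
        return p.copy()
    return multipletests(p, method="fdr_bh")[1]


def univariate_cox_scan(
    X, times, events, max_iter: int = 40, tol: float = 1e-10
) -> pd.DataFrame:
    """One-covariate Cox fits for every column of X, vectorized.

    Newton-Raphson on the Breslow partial likelihood, run simultaneously for
    all features (each feature gets its own scalar coefficient).  Intended
    for screening panels of genes or gene pairs; with continuous follow-up
    times (no ties) the Breslow and Efron likelihoods coincide.

    Returns a DataFrame with columns coef, hr, se, z, p, converged; constant
    columns get NaN statistics and converged = False.
    """
    t, e = check_survival(times, events)
    if isinstance(X, pd.DataFrame):
        names = list(X.columns)
        x = X.to_numpy(dtype=float)
    else:
        x = np.asarray(X, dtype=float)
        if x.ndim == 1:
            x = x[:, None]
        names = [f"x{i}" for i in range(x.shape[1])]
    n, p = x.shape
    if n != len(t):
        raise ValidationError("feature matrix and survival data differ in length")

    order = np.argsort(t, kind="stable")
    xs = x[order]
    es = e[order]
    ts = t[order]
    # map each row to the first index sharing its time (risk-set boundary)
    left = np.searchsorted(ts, ts, side="left")
    ev = es == 1
    n_events = int(ev.sum())

    variable = xs.std(axis=0) > 0
    beta = np.zeros(p)
    active = variable.copy()
    for _ in range(max_iter):
        if not active.any():
            break
        w = np.exp(np.clip(xs[:, active] * beta[active], -500, 500))
        xw = xs[:, active] * w
        x2w = xs[:, active] * xw
        # suffix sums -> risk-set aggregates at each time boundary
        s0 = np.cumsum(w[::-1], axis=0)[::-1]
        s1 = np.cumsum(xw[::-1], axis=0)[::-1]
        s2 = np.cumsum(x2w[::-1], axis=0)[::-1]
        s0e, s1e, s2e = s0[left][ev], s1[left][ev], s2[left][ev]
        mean = s1e / s0e
        grad = (xs[:, active][ev] - mean).sum(axis=0)
        info = (s2e / s0e - mean**2).sum(axis=0)
        info = np.maximum(info, 1e-12)
        step = np.clip(grad / info, -1.5, 1.5)
        beta[active] += step
        still = np.abs(step) > tol
        idx = np.flatnonzero(active)
        active[idx[~still]] = False

    # final information for SEs at the fitted beta
    se = np.full(p, np.nan)
    z = np.full(p, np.nan)
    if variable.any():
        w = np.exp(np.clip(xs[:, variable] * beta[variable], -500, 500))
        xw = xs[:, variable] * w
        x2w = xs[:, variable] * xw
        s0 = np.cumsum(w[::-1], axis=0)[::-1]
        s1 = np.cumsum(xw[::-1], axis=0)[::-1]
        s2 = np.cumsum(x2w[::-1], axis=0)[::-1]
        mean = s1[left][ev] / s0[left][ev]
        info = (s2[left][ev] / s0[left][ev] - mean**2).sum(axis=0)
        info = np.maximum(info, 1e-12)
        se[variable] = 1.0 / np.sqrt(info)
        z[variable] = beta[variable] / se[variable]
    diverged = np.abs(beta) > 12  # monotone likelihood guard
    converged = variable & ~diverged
    pvals = np.where(np.isnan(z), np.nan, 2 * stats.norm.sf(np.abs(z)))
    out = pd.DataFrame(
        {
            "coef": np.where(variable, beta, np.nan),
            "hr": np.where(variable, np.exp(beta), np.nan),
            "se": se,
            "z": z,
            "p": pvals,
            "converged": converged,
        },
        index=pd.Index(names, name="feature"),
    )
    out.attrs["n_events"] = n_events
    return out


def screen_genes(
    expr: pd.DataFrame,
    times,
    events,
    genes=None,
    p_threshold: float = 0.01,
    rule: str = "union",
    minprop: float = 0.10,
    selection_adjusted: bool = True,
) -> pd.DataFrame:
    """Univariate prognostic screen of candidate genes.

    For each gene: a one-covariate Cox fit (p_cox) and a Kaplan-Meier
    comparison at the gene's maximally selected cutpoint (p_km).  By
    default p_km is adjusted for the cutpoint search with the
    Miller–Siegmund approximation (:func:`maxstat_pvalue`); pass
    ``selection_adjusted=False`` for the raw chi-square p of the best
    split, a known anti-conservative choice.  A gene passes when
    ``p_cox < p_threshold`` or ``p_km < p_threshold`` (``rule='union'``,
    the default) or when both do (``rule='intersection'``).

    Constant genes are skipped with a warning.  Returns one row per
    screened gene: coef, hr, p_cox, cutpoint, p_km, passed.
    """
    t, e = check_survival(times, events)
    if rule not in ("union", "intersection"):
        raise ValidationError(f"unknown screening rule {rule!r}")
    if genes is None:
        genes = list(expr.index)
    genes = [g for g in dict.fromkeys(genes)]
    missing = [g for g in genes if g not in expr.index]
    if missing:
        raise ValidationError(f"candidate genes absent from expression matrix: {missing}")
    sub = expr.loc[genes]
    constant = sub.index[sub.nunique(axis=1) <= 1].tolist()
    if constant:
        warnings.warn(f"skipping constant genes: {constant}", stacklevel=2)
        sub = sub.drop(index=constant)
    if sub.empty:
        raise ValidationError("no non-constant candidate genes to screen")

    cox = univariate_cox_scan(sub.T, t, e)
    cutpoints = np.full(len(sub), np.nan)
    p_km = np.full(len(sub), np.nan)
    for i, g in enumerate(sub.index):
        try:
            cp = max_selected_cutpoint(sub.loc[g].to_numpy(), t, e, minprop=minprop)
        except ValidationError:
            continue  # no admissible split; gene judged on Cox p alone
        cutpoints[i] = cp.threshold
        if selection_adjusted:
            p_km[i] = maxstat_pvalue(cp.statistic, minprop=minprop)
        else:
            p_km[i] = stats.chi2.sf(cp.statistic**2, 1)
    p_cox = cox["p"].to_numpy()
    below_cox = (p_cox < p_threshold) & ~np.isnan(p_cox)
    below_km = (p_km < p_threshold) & ~np.isnan(p_km)
    passed = below_cox | below_km if rule == "union" else below_cox & below_km
    out = pd.DataFrame(
        {
            "coef": cox["coef"].to_numpy(),
            "hr": cox["hr"].to_numpy(),
            "p_cox": p_cox,
            "cutpoint": cutpoints,
            "p_km": p_km,
            "passed": passed,
        },
        index=pd.Index(sub.index, name="gene"),
    )
    logger.info("screened %d genes: %d passed at p<%g (%s rule)",
                len(out), int(passed.sum()), p_threshold, rule)
    return out
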