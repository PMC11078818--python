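"""Nested penalized-Cox construction of the gene-pair risk signature.

The training pipeline, in order:

1. univariate screen of the candidate (cell-death) genes — Cox or
   optimal-cutpoint KM p below a threshold (default 0.01, union rule);
2. stage-1 LASSO-Cox on the screened genes' expression (cross-validated
   partial-likelihood deviance, 1-SE lambda by default) -> anchor genes;
3. pair coding of anchors against the partner transcriptome;
4. frequency filter retaining pairs coded +1 in 20-80% of samples;
5. per-pair univariate Cox with BH-FDR retention (default q < 0.05);
6. stage-2 LASSO-Cox on the retained +/-1 pair features -> final pairs and
   coefficients;
7. maximally selected cutpoint on the training risk scores -> risk cutoff.

The resulting risk score is ``sum(coef * pair_value)`` over the selected
pairs; samples scoring above the training cutoff are called high-risk, and
the cutoff is carried unchanged to validation cohorts.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold
from sksurv.linear_model import CoxnetSurvivalAnalysis
from sksurv.util import Surv

from .errors import StageError, ValidationError
from .pairing import GenePairMatrix, build_pair_matrix, filter_pairs_by_frequency
from .survstats import (
    bh_fdr,
    check_survival,
    max_selected_cutpoint,
    screen_genes,
    univariate_cox_scan,
)

__all__ = [
    "PairModel",
    "TrainConfig",
    "LassoPathResult",
    "lasso_cox_path",
    "train_cell_death_model",
    "compute_risk_scores",
]

logger = logging.getLogger(__name__)


@dataclass
class PairModel:
    """A fitted gene-pair Cox signature: pairs, coefficients, risk cutoff."""

    pairs: list[tuple[str, str]]
    coefficients: np.ndarray
    risk_cutoff: float
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        self.coefficients = np.asarray(self.coefficients, dtype=float)
        if len(self.pairs) != len(self.coefficients):
            raise ValidationError("pairs and coefficients differ in length")
        if len(self.pairs) == 0:
            raise ValidationError("a pair model needs at least one pair")
        if not np.isfinite(self.coefficients).all() or (self.coefficients == 0).any():
            raise ValidationError("coefficients must be finite and nonzero")
        if not np.isfinite(self.risk_cutoff):
            raise ValidationError("risk cutoff must be finite")

    @property
    def genes(self) -> list[str]:
        out: list[str] = []
        for a, b in self.pairs:
            for g in (a, b):
                if g not in out:
                    out.append(g)
        return out


@dataclass
class TrainConfig:
    """Tunable parameters of the signature-construction pipeline."""

    p_threshold: float = 0.01       # univariate gene-screen threshold
    screen_rule: str = "union"      # 'union': Cox OR optimal-cutpoint KM
    freq_low: float = 0.20          # pair +1-frequency filter, inclusive
    freq_high: float = 0.80
    pair_fdr: float = 0.05          # BH q threshold for pair retention
    lambda_stage1: str = "1se"      # lambda rule for the gene-level LASSO
    lambda_stage2: str = "1se"      # lambda rule for the pair-level LASSO
    minprop: float = 0.10           # cutpoint minimum group proportion
    n_folds: int = 10
    seed: int = 0


def _breslow_loglik(beta: np.ndarray, X: np.ndarray, times: np.ndarray,
                    events: np.ndarray) -> float:
    """Breslow partial log-likelihood at coefficient vector beta."""
    order = np.argsort(times, kind="stable")
    xs = X[order]
    es = events[order] == 1
    ts = times[order]
    eta = xs @ beta
    eta = np.clip(eta, -500, 500)
    w = np.exp(eta)
    s0 = np.cumsum(w[::-1])[::-1]
    left = np.searchsorted(ts, ts, side="left")
    return float((eta[es] - np.log(s0[left][es])).sum())


@dataclass
class LassoPathResult:
    """Cross-validated L1 Cox path and the active set at the chosen lambda."""

    alphas: np.ndarray
    cv_mean: np.ndarray
    cv_se: np.ndarray
    alpha_min: float
    alpha_1se: float
    chosen_alpha: float
    coefficients: pd.Series  # nonzero coefficients on the input scale

    @property
    def selected(self) -> list[str]:
        return list(self.coefficients.index)


def lasso_cox_path(
    X,
    times,
    events,
    lambda_rule: str = "1se",
    n_folds: int = 10,
    seed: int = 0,
    standardize: bool = True,
) -> LassoPathResult:
    """L1-penalized Cox with K-fold cross-validated deviance lambda choice.

    The path is fitted on the full data (coordinate-descent elastic net with
    l1_ratio = 1); per-fold deviance uses the Verweij–Van Houwelingen
    cross-validated partial likelihood, dev_k(lambda) =
    -2 [ pl_full(beta_k) - pl_train(beta_k) ], which stays well-defined for
    small test folds.  Folds are stratified by event status and seeded, so
    the selection is deterministic.

    lambda_rule 'min' picks the deviance-minimizing lambda; '1se' the
    largest lambda whose mean deviance is within one standard error of the
    minimum.  An empty active set is permitted (warning, not error).
    """
    t, e = check_survival(times, events)
    if lambda_rule not in ("min", "1se"):
        raise ValidationError(f"lambda_rule must be 'min' or '1se', got {lambda_rule!r}")
    if isinstance(X, pd.DataFrame):
        names = list(X.columns)
        x = X.to_numpy(dtype=float)
    else:
        x = np.asarray(X, dtype=float)
        names = [f"x{i}" for i in range(x.shape[1])]
    n, p = x.shape
    if n != len(t):
        raise ValidationError("feature matrix and survival data differ in length")
    if e.sum() < 2 * n_folds:
        raise ValidationError(
            f"{int(e.sum())} events cannot support {n_folds}-fold CV "
            "(need >= 2 events per fold on average)"
        )
    scale = x.std(axis=0, ddof=0)
    if standardize:
        keep_scale = np.where(scale > 0, scale, 1.0)
        xw = (x - x.mean(axis=0)) / keep_scale
    else:
        keep_scale = np.ones(p)
        xw = x
    y = Surv.from_arrays(event=e.astype(bool), time=t)

    full = CoxnetSurvivalAnalysis(l1_ratio=1.0, n_alphas=100, fit_baseline_model=False)
    full.fit(xw, y)
    alphas = np.asarray(full.alphas_)

    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    devs = np.full((n_folds, len(alphas)), np.nan)
    for k, (tr, _te) in enumerate(skf.split(xw, e)):
        fold = CoxnetSurvivalAnalysis(l1_ratio=1.0, alphas=alphas,
                                      fit_baseline_model=False)
        try:
            fold.fit(xw[tr], Surv.from_arrays(event=e[tr].astype(bool), time=t[tr]))
        except Exception as exc:  # pragma: no cover - rare path failure
            raise RuntimeError(f"penalized Cox path failed on fold {k}: {exc}") from exc
        coefs = fold.coef_  # (p, n_alphas_fit)
        fitted = np.asarray(fold.alphas_)
        for j, a in enumerate(alphas):
            jj = int(np.argmin(np.abs(fitted - a)))
            beta = coefs[:, jj]
            devs[k, j] = -2.0 * (
                _breslow_loglik(beta, xw, t, e) - _breslow_loglik(beta, xw[tr], t[tr], e[tr])
            )
    cv_mean = devs.mean(axis=0)
    cv_se = devs.std(axis=0, ddof=1) / np.sqrt(n_folds)
    i_min = int(np.nanargmin(cv_mean))
    alpha_min = float(alphas[i_min])
    within = cv_mean <= cv_mean[i_min] + cv_se[i_min]
    alpha_1se = float(alphas[np.flatnonzero(within)[0]])  # alphas descend from large
    chosen = alpha_min if lambda_rule == "min" else alpha_1se
    j = int(np.argmin(np.abs(alphas - chosen)))
    beta = full.coef_[:, j] / keep_scale
    nz = np.flatnonzero(beta != 0)
    if len(nz) == 0:
        warnings.warn("penalized Cox selected an empty active set", stacklevel=2)
    coef = pd.Series(beta[nz], index=[names[i] for i in nz], name="coef")
    logger.info("lasso path: %d features -> %d active at lambda_%s=%.5g",
                p, len(nz), lambda_rule, chosen)
    return LassoPathResult(
        alphas=alphas, cv_mean=cv_mean, cv_se=cv_se,
        alpha_min=alpha_min, alpha_1se=alpha_1se, chosen_alpha=float(chosen),
        coefficients=coef,
    )


def train_cell_death_model(
    expr: pd.DataFrame,
    clinical: pd.DataFrame,
    candidate_genes,
    config: TrainConfig | None = None,
    partner_genes=None,
) -> PairModel:
    """Run the full nested pipeline and return the fitted :class:`PairModel`.

    ``clinical`` must carry os_time/os_event indexed by sample id;
    ``candidate_genes`` is the curated cell-death gene list.  Any stage that
    yields zero features aborts with a :class:`StageError` naming the stage.
    """
    from .io import align_samples

    cfg = config or TrainConfig()
    expr, clinical, align_report = align_samples(expr, clinical)
    t, e = check_survival(clinical["os_time"], clinical["os_event"])

    candidates = [g for g in dict.fromkeys(candidate_genes) if g in expr.index]
    if not candidates:
        raise StageError("gene screening", "no candidate genes present in the expression matrix")

    screen = screen_genes(expr, t, e, genes=candidates,
                          p_threshold=cfg.p_threshold, rule=cfg.screen_rule,
                          minprop=cfg.minprop)
    screened = screen.index[screen["passed"]].tolist()
    logger.info("stage 1 screen: %d/%d genes passed", len(screened), len(candidates))
    if not screened:
        raise StageError("gene screening", "zero genes passed the univariate screen")

    if len(screened) == 1:
        anchors = screened  # nothing left to penalize away
    else:
        path1 = lasso_cox_path(expr.loc[screened].T, t, e,
                               lambda_rule=cfg.lambda_stage1,
                               n_folds=cfg.n_folds, seed=cfg.seed, standardize=True)
        anchors = path1.selected
    logger.info("stage 2 gene LASSO: %d anchor genes", len(anchors))
    if not anchors:
        raise StageError("gene LASSO", "penalized selection retained zero anchor genes")

    gpm = build_pair_matrix(expr, anchors, partner_genes=partner_genes)
    logger.info("stage 3 pairing: %d candidate pairs", gpm.n_pairs)

    gpm, freq_report = filter_pairs_by_frequency(gpm, cfg.freq_low, cfg.freq_high)
    logger.info("stage 4 frequency filter: %d pairs retained", gpm.n_pairs)
    if gpm.n_pairs == 0:
        raise StageError("frequency filter", "zero pairs in the admissible frequency band")

    pair_df = pd.DataFrame(gpm.values.T.astype(float), columns=gpm.pair_labels)
    pair_cox = univariate_cox_scan(pair_df, t, e)
    usable = ~pair_cox["p"].isna()
    q = np.full(len(pair_cox), np.nan)
    q[usable.to_numpy()] = bh_fdr(pair_cox.loc[usable, "p"].to_numpy())
    keep = usable.to_numpy() & (q < cfg.pair_fdr)
    logger.info("stage 5 pair FDR: %d/%d pairs at q<%g", int(keep.sum()),
                gpm.n_pairs, cfg.pair_fdr)
    if not keep.any():
        raise StageError("pair FDR retention", "zero pairs below the FDR threshold")
    kept_pairs = [p for p, k in zip(gpm.pairs, keep) if k]
    kept_values = gpm.values[keep]
    kept_labels = [f"{a}|{b}" for a, b in kept_pairs]

    path2 = lasso_cox_path(
        pd.DataFrame(kept_values.T.astype(float), columns=kept_labels),
        t, e, lambda_rule=cfg.lambda_stage2, n_folds=cfg.n_folds,
        seed=cfg.seed, standardize=False,  # +/-1 features are scale-homogeneous
    )
    if not path2.selected:
        raise StageError("pair LASSO", "penalized selection retained zero pairs")
    label_to_pair = dict(zip(kept_labels, kept_pairs))
    final_pairs = [label_to_pair[lab] for lab in path2.selected]
    coefs = path2.coefficients.to_numpy()
    logger.info("stage 6 pair LASSO: %d pairs in the final signature", len(final_pairs))

    value_rows = np.array([kept_values[kept_labels.index(lab)] for lab in path2.selected])
    train_scores = coefs @ value_rows
    cut = max_selected_cutpoint(train_scores, t, e, minprop=cfg.minprop)
    logger.info("stage 7 cutpoint: %.4g (|z|=%.3g, groups %d/%d)",
                cut.threshold, cut.statistic, cut.n_low, cut.n_high)

    provenance = dict(asdict(cfg))
    provenance.update(
        n_samples=len(t),
        n_candidates=len(candidates),
        n_screened=len(screened),
        n_anchors=len(anchors),
        anchor_genes=list(anchors),
        n_pairs_built=int(len(freq_report)),
        n_pairs_frequency=int((freq_report["kept"]).sum()),
        n_pairs_fdr=len(kept_pairs),
        n_pairs_final=len(final_pairs),
        alignment=align_report,
    )
    return PairModel(pairs=final_pairs, coefficients=coefs,
                     risk_cutoff=float(cut.threshold), provenance=provenance)


def compute_risk_scores(model: PairModel, expr: pd.DataFrame) -> pd.DataFrame:
    """Score samples with a fitted model: RiskScore = sum(coef * pair value).

    Pair values (+1/-1) are recomputed from the supplied expression matrix;
    group 'high' iff score > model.risk_cutoff (the training cutoff is
    applied unchanged to new cohorts).  Missing model genes are an error —
    no imputation.
    """
    missing = [g for g in model.genes if g not in expr.index]
    if missing:
        raise ValidationError(f"model genes absent from expression matrix: {missing}")
    scores = np.zeros(expr.shape[1])
    for (a, b), c in zip(model.pairs, model.coefficients):
        vals = np.where(expr.loc[a].to_numpy() > expr.loc[b].to_numpy(), 1.0, -1.0)
        scores += c * vals
    group = np.where(scores > model.risk_cutoff, "high", "low")
    return pd.DataFrame(
        {"risk_score": scores, "risk_group": group},
        index=pd.Index(expr.columns, name="sample_id"),
    )
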