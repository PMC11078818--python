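"""Multi-cohort synthetic myeloma-like data with known pair-level truth.

Each cohort is a genes x samples expression matrix plus a clinical table
(overall-survival time in months, event indicator, ISS stage).  The data
generating process mirrors the assumptions of the pair-signature analysis:

* gene-wise heterogeneous continuous expression (normal / log-normal /
  gamma marginals with per-cohort parameters, emulating platform
  differences);
* a designated set of informative gene pairs whose +/-1 relative-order
  coding drives a linear predictor eta = sum(beta * pair value);
* survival from a proportional-hazards model with exponential baseline,
  times drawn by inverse-transform sampling;
* independent uniform censoring on (0, C), with C solved numerically so the
  expected censored fraction hits the configured target;
* ISS stages from a cumulative-logit model whose latent location increases
  with eta, so stage and hazard are positively associated.

Per-sample monotone distortions (affine / power / log shifts) can be layered
on any cohort to emulate batch and platform effects; they change raw values
but never the within-sample gene ranking.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .errors import ValidationError

__all__ = [
    "SimulationConfig",
    "MonotoneTransform",
    "simulate_cohort",
    "simulate_cohorts",
    "apply_batch_transform",
]


@dataclass(frozen=True)
class MonotoneTransform:
    """A strictly increasing distortion applied to one sample's values.

    kinds: 'identity'; 'affine' (a*x + b, a > 0); 'power' (x**p, p > 0,
    positive data); 'log1p' (positive data); 'log_shift' (log(x + shift)).
    """

    kind: str = "identity"
    a: float = 1.0
    b: float = 0.0
    p: float = 1.0
    shift: float = 0.0

    def __post_init__(self):
        if self.kind not in ("identity", "affine", "power", "log1p", "log_shift"):
            raise ValidationError(f"unknown transform kind {self.kind!r}")
        if self.kind == "affine" and self.a <= 0:
            raise ValidationError("affine transform needs slope a > 0 to be increasing")
        if self.kind == "power" and self.p <= 0:
            raise ValidationError("power transform needs exponent p > 0")

    def apply(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        if self.kind == "identity":
            return x.copy()
        if self.kind == "affine":
            return self.a * x + self.b
        if self.kind == "power":
            if (x <= 0).any():
                raise ValidationError("power transform requires strictly positive values")
            return x ** self.p
        if self.kind == "log1p":
            if (x <= -1).any():
                raise ValidationError("log1p transform requires values > -1")
            return np.log1p(x)
        if (x + self.shift <= 0).any():
            raise ValidationError("log_shift transform requires x + shift > 0")
        return np.log(x + self.shift)


@dataclass
class SimulationConfig:
    """Study conditions for one synthetic cohort.

    Defaults reflect a mid-sized myeloma expression cohort: a few hundred
    patients, heavy right-censoring (about 65% alive at last follow-up),
    an exponential baseline hazard of 0.02/month (median OS near three
    years at eta = 0), and informative-pair effects between 0.3 and 1.0 on
    the log-hazard scale.
    """

    n_samples: int = 400
    n_genes: int = 120
    n_informative_pairs: int = 10
    pair_coefficients: np.ndarray | None = None  # default: |beta| in [0.3, 1.0], alternating sign
    baseline_hazard: float = 0.02       # events per month at eta = 0
    censoring_rate: float = 0.65        # target censored fraction
    iss_association_strength: float = 1.5  # latent shift of the ISS cumulative-logit
    batch_transform: MonotoneTransform | list | None = None
    seed: int = 0

    def __post_init__(self):
        if self.n_informative_pairs > self.n_genes * (self.n_genes - 1) // 2:
            raise ValidationError("more informative pairs than gene pairs exist")
        if 2 * self.n_informative_pairs > self.n_genes:
            raise ValidationError(
                "informative pairs are drawn from disjoint genes: need n_genes >= 2 * n_informative_pairs"
            )
        if not (0 <= self.censoring_rate < 1):
            raise ValidationError("censoring_rate must lie in [0, 1)")
        if self.baseline_hazard <= 0:
            raise ValidationError("baseline_hazard must be positive")
        if self.iss_association_strength < 0:
            raise ValidationError("iss_association_strength must be non-negative")
        if self.pair_coefficients is not None:
            beta = np.asarray(self.pair_coefficients, dtype=float)
            if beta.shape != (self.n_informative_pairs,):
                raise ValidationError(
                    f"pair_coefficients must have length {self.n_informative_pairs}"
                )
            object.__setattr__(self, "pair_coefficients", beta)

    def resolved_coefficients(self) -> np.ndarray:
        if self.pair_coefficients is not None:
            return np.asarray(self.pair_coefficients, dtype=float)
        k = self.n_informative_pairs
        if k == 0:
            return np.zeros(0)
        mags = np.linspace(0.3, 1.0, k)
        signs = np.where(np.arange(k) % 2 == 0, 1.0, -1.0)
        return mags * signs


def _gene_ids(n: int) -> list[str]:
    width = max(4, len(str(n)))
    return [f"G{i:0{width}d}" for i in range(1, n + 1)]


def _draw_expression(cfg: SimulationConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Heterogeneous gene-wise marginals; informative-pair genes share a
    family so their relative order is informative but not degenerate."""
    genes = _gene_ids(cfg.n_genes)
    samples = [f"S{cfg.seed}_{j:04d}" for j in range(1, cfg.n_samples + 1)]
    mat = np.empty((cfg.n_genes, cfg.n_samples))

    k = cfg.n_informative_pairs
    for p in range(k):
        # genes 2p and 2p+1 form truth pair p; near-matched normal marginals
        mu = rng.uniform(3, 9)
        sigma = rng.uniform(0.6, 1.6)
        # offset chosen so P(A > B) lands in ~(0.3, 0.7): survives the
        # 20-80% frequency filter with room to spare
        delta = sigma * np.sqrt(2) * rng.normal(0, 0.25)
        mat[2 * p] = rng.normal(mu, sigma, cfg.n_samples)
        mat[2 * p + 1] = rng.normal(mu + delta, sigma, cfg.n_samples)
    for i in range(2 * k, cfg.n_genes):
        family = rng.choice(("normal", "lognormal", "gamma"), p=(0.5, 0.3, 0.2))
        if family == "normal":
            mat[i] = rng.normal(rng.uniform(2, 10), rng.uniform(0.5, 2.0), cfg.n_samples)
        elif family == "lognormal":
            mat[i] = rng.lognormal(rng.uniform(0.5, 2.0), rng.uniform(0.3, 0.8), cfg.n_samples)
        else:
            mat[i] = rng.gamma(rng.uniform(1.0, 5.0), rng.uniform(0.5, 2.0), cfg.n_samples)
    df = pd.DataFrame(mat, index=genes, columns=samples)
    if (df.nunique(axis=1) <= 1).any():
        raise ValidationError("degenerate (constant) gene generated")  # pragma: no cover
    return df


def _solve_censoring_bound(t: np.ndarray, target: float) -> float:
    """Upper bound C of Uniform(0, C) censoring hitting the target rate.

    With censor time U(0, C), P(censored | T = t) = min(t / C, 1); the
    expectation over the drawn event times is monotone decreasing in C, so
    a root always exists for target in (0, 1).
    """

    def rate(c):
        return float(np.minimum(t / c, 1.0).mean()) - target

    lo, hi = 1e-9, float(t.max()) * 2
    while rate(hi) > 0:
        hi *= 2
        if hi > 1e12:
            raise ValidationError("infeasible censoring target")  # pragma: no cover
    return brentq(rate, lo, hi, xtol=1e-10)


def simulate_cohort(config: SimulationConfig):
    """Generate one cohort.

    Returns
    -------
    expr : DataFrame
        Genes x samples, after any configured batch transform.
    clinical : DataFrame
        Indexed by sample id: os_time (months), os_event, iss, age, gender.
    truth : dict
        'pairs' (list of (geneA, geneB)), 'beta', 'eta' (per-sample linear
        predictor), 'censoring_bound'.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    expr = _draw_expression(cfg, rng)
    genes = list(expr.index)
    beta = cfg.resolved_coefficients()
    truth_pairs = [(genes[2 * p], genes[2 * p + 1]) for p in range(cfg.n_informative_pairs)]

    eta = np.zeros(cfg.n_samples)
    for (a, b), bta in zip(truth_pairs, beta):
        vals = np.where(expr.loc[a].to_numpy() > expr.loc[b].to_numpy(), 1.0, -1.0)
        eta += bta * vals

    u = rng.uniform(size=cfg.n_samples)
    t_event = -np.log(u) / (cfg.baseline_hazard * np.exp(eta))
    if cfg.censoring_rate == 0:
        os_time, os_event = t_event, np.ones(cfg.n_samples, dtype=int)
        c_bound = np.inf
    else:
        c_bound = _solve_censoring_bound(t_event, cfg.censoring_rate)
        t_cens = rng.uniform(0, c_bound, cfg.n_samples)
        os_event = (t_event <= t_cens).astype(int)
        os_time = np.minimum(t_event, t_cens)

    # ISS: cumulative-logit latent with a non-negative, strength-scaled
    # shift.  eta is mapped to [0, 2] via its deterministic bounds
    # +/- sum|beta| so increasing the strength shifts every sample's latent
    # upward (stochastic ordering toward stage 3) while keeping stage
    # positively associated with hazard.
    bound = float(np.abs(beta).sum())
    eta_unit = (eta + bound) / (2 * bound) if bound > 0 else np.full(cfg.n_samples, 0.5)
    latent = cfg.iss_association_strength * 2.0 * eta_unit + rng.logistic(size=cfg.n_samples)
    c1, c2 = -np.log(2.0), np.log(2.0)  # equal thirds at strength 0
    iss = np.where(latent < c1, 1, np.where(latent < c2, 2, 3))

    clinical = pd.DataFrame(
        {
            "os_time": os_time,
            "os_event": os_event,
            "iss": iss.astype(float),
            "age": np.round(rng.normal(63, 9, cfg.n_samples)).clip(25, 92),
            "gender": rng.choice(("female", "male"), size=cfg.n_samples, p=(0.4, 0.6)),
        },
        index=pd.Index(expr.columns, name="sample_id"),
    )
    if cfg.batch_transform is not None:
        expr = apply_batch_transform(expr, cfg.batch_transform)
    truth = {
        "pairs": truth_pairs,
        "beta": beta,
        "eta": eta,
        "censoring_bound": c_bound,
    }
    return expr, clinical, truth


def simulate_cohorts(config: SimulationConfig, n_cohorts: int,
                     batch_transforms=None) -> list[tuple]:
    """Generate several cohorts sharing gene universe and true pair effects.

    Cohort c reuses the config with seed ``seed + 7919 * c`` (deterministic
    perturbation) and, optionally, its own batch transform, emulating
    platform-distinct cohorts measuring the same biology.
    """
    if batch_transforms is not None and len(batch_transforms) != n_cohorts:
        raise ValidationError("need one batch transform (or None) per cohort")
    out = []
    for c in range(n_cohorts):
        cfg = replace(
            config,
            seed=config.seed + 7919 * c,
            batch_transform=batch_transforms[c] if batch_transforms is not None
            else config.batch_transform,
        )
        out.append(simulate_cohort(cfg))
    return out


def apply_batch_transform(expr: pd.DataFrame, transform) -> pd.DataFrame:
    """Apply a strictly increasing distortion to each sample (column).

    ``transform`` is a single :class:`MonotoneTransform` (shared by all
    samples) or a list with one transform per sample.  Shape and ids are
    preserved and, by monotonicity, so is every within-sample gene ranking.
    """
    n_samples = expr.shape[1]
    if isinstance(transform, MonotoneTransform):
        transforms = [transform] * n_samples
    else:
        transforms = list(transform)
        if len(transforms) != n_samples:
            raise ValidationError(
                f"got {len(transforms)} transforms for {n_samples} samples"
            )
        if not all(isinstance(tr, MonotoneTransform) for tr in transforms):
            raise ValidationError("transforms must be MonotoneTransform instances")
    cols = [tr.apply(expr.iloc[:, j].to_numpy()) for j, tr in enumerate(transforms)]
    return pd.DataFrame(np.column_stack(cols), index=expr.index, columns=expr.columns)
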