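"""Fusion of the binary pair-signature risk group with ISS.

Crossing risk {high, low} with ISS {1, 2, 3} yields six strata
(``low_1`` ... ``high_3``); these collapse into a three-tier refined
staging — low = {low_1, low_2}, medium = {high_1, low_3},
high = {high_2, high_3}.  The merge is a fixed published mapping, not
re-derived per dataset; :func:`stratum_logrank_table` lets users check
whether their own data supports it.
"""

from __future__ import annotations

import itertools
import logging

import numpy as np
import pandas as pd

from .errors import ValidationError
from .survstats import logrank_test

__all__ = [
    "RISK_GROUPS",
    "STRATUM_LABELS",
    "REFINED_ISS_MAP",
    "combine_strata",
    "refine_iss",
    "stratum_logrank_table",
]

logger = logging.getLogger(__name__)

RISK_GROUPS = ("low", "high")
STRATUM_LABELS = tuple(f"{r}_{s}" for r in RISK_GROUPS for s in (1, 2, 3))

#: Six strata -> three refined tiers.
REFINED_ISS_MAP = {
    "low_1": "low",
    "low_2": "low",
    "high_1": "medium",
    "low_3": "medium",
    "high_2": "high",
    "high_3": "high",
}

#: Ordinal encoding of the refined tiers (rank-based comparisons).
REFINED_ORDINAL = {"low": 1, "medium": 2, "high": 3}


def combine_strata(risk_group, iss) -> tuple[pd.Series, dict]:
    """Label each sample ``{risk}_{iss}``; samples lacking ISS are excluded.

    Returns (labels, report) where report counts excluded samples.  Invalid
    risk groups or ISS stages outside {1, 2, 3} are errors.
    """
    rg = pd.Series(risk_group)
    stage = pd.Series(iss)
    if len(rg) != len(stage):
        raise ValidationError("risk_group and iss must have equal length")
    if isinstance(iss, pd.Series) and isinstance(risk_group, pd.Series):
        if not rg.index.equals(stage.index):
            raise ValidationError("risk_group and iss indexes differ")
    bad_risk = ~rg.isin(RISK_GROUPS)
    if bad_risk.any():
        raise ValidationError(f"invalid risk groups: {sorted(rg[bad_risk].unique())}")
    has_iss = stage.notna()
    valid = stage[has_iss]
    if not valid.isin([1, 2, 3]).all():
        bad = sorted(valid[~valid.isin([1, 2, 3])].unique())
        raise ValidationError(f"ISS stages outside {{1,2,3}}: {bad}")
    n_excluded = int((~has_iss).sum())
    if n_excluded:
        logger.warning("excluding %d samples without ISS from staging", n_excluded)
    labels = rg[has_iss].astype(str) + "_" + valid.astype(int).astype(str)
    labels.name = "stratum"
    return labels, {"n_staged": int(has_iss.sum()), "n_excluded_missing_iss": n_excluded}


def refine_iss(strata) -> pd.Series:
    """Collapse six risk-by-ISS strata into the three refined tiers."""
    s = pd.Series(strata).astype(str)
    unknown = sorted(set(s.unique()) - set(REFINED_ISS_MAP))
    if unknown:
        raise ValidationError(f"unknown strata: {unknown}")
    out = s.map(REFINED_ISS_MAP)
    out.name = "refined_iss"
    return out


def stratum_logrank_table(strata, times, events) -> pd.DataFrame:
    """Pairwise log-rank p-values between the observed strata.

    Exploratory check of whether the fixed six-to-three merge is supported:
    strata merged into one tier should show large p, strata in different
    tiers small p.  Pairs where either stratum has no events get NaN.
    """
    s = pd.Series(strata).astype(str).to_numpy()
    t = np.asarray(times, dtype=float)
    e = np.asarray(events).astype(int)
    labels = sorted(np.unique(s))
    table = pd.DataFrame(np.nan, index=labels, columns=labels)
    for a, b in itertools.combinations(labels, 2):
        mask = (s == a) | (s == b)
        if e[mask].sum() == 0:
            continue
        try:
            res = logrank_test(s[mask], t[mask], e[mask])
        except ValidationError:
            continue
        table.loc[a, b] = table.loc[b, a] = res.p
    for lab in labels:
        table.loc[lab, lab] = 1.0
    return table
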