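"""Binary gene-pair features from within-sample expression order.

A gene pair (A, B) is coded +1 in a sample where A's expression strictly
exceeds B's and -1 otherwise.  Because the coding depends only on the
relative order of two measurements taken in the *same* sample, it is exactly
invariant under any strictly increasing per-sample transformation of the
expression values — the property that makes pair features portable across
microarray/RNA-seq platforms and robust to batch effects.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ValidationError

__all__ = ["GenePairMatrix", "build_pair_matrix", "filter_pairs_by_frequency"]


@dataclass
class GenePairMatrix:
    """Pair-by-sample matrix of values in {+1, -1}.

    Attributes
    ----------
    pairs
        Ordered (anchor, partner) gene-symbol tuples, one per row.
    sample_ids
        Column identifiers, aligned with ``values``.
    values
        int8 array of shape (n_pairs, n_samples) with entries +1 or -1.
    """

    pairs: list[tuple[str, str]]
    sample_ids: list[str]
    values: np.ndarray = field(repr=False)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.int8)
        if self.values.shape != (len(self.pairs), len(self.sample_ids)):
            raise ValidationError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.pairs)} pairs x {len(self.sample_ids)} samples"
            )
        if self.values.size and not np.isin(self.values, (-1, 1)).all():
            raise ValidationError("pair values must all be +1 or -1")
        seen: set[frozenset] = set()
        for a, b in self.pairs:
            if a == b:
                raise ValidationError(f"self-pair {a}|{b} is not allowed")
            key = frozenset((a, b))
            if key in seen:
                raise ValidationError(f"duplicate unordered pair {a}|{b}")
            seen.add(key)

    @property
    def n_pairs(self) -> int:
        return len(self.pairs)

    @property
    def pair_labels(self) -> list[str]:
        return [f"{a}|{b}" for a, b in self.pairs]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.pair_labels, columns=self.sample_ids)

    def frequencies(self) -> np.ndarray:
        """Per-pair fraction of samples coded +1."""
        return (self.values == 1).mean(axis=1)


def build_pair_matrix(
    expr: pd.DataFrame,
    anchor_genes,
    partner_genes=None,
) -> GenePairMatrix:
    """Code every (anchor, partner) pair as +1/-1 per sample.

    Parameters
    ----------
    expr
        Genes x samples expression matrix (any per-sample monotone scale).
    anchor_genes
        Genes forming the first element of each pair (in a trained signature,
        the screened prognostic genes).
    partner_genes
        Candidate second elements; defaults to every gene in ``expr``, so each
        anchor is paired with every other gene, anchors included.  Self-pairs
        are skipped and each unordered pair is emitted once (anchored
        orientation, first anchor in sort order wins).

    Returns
    -------
    GenePairMatrix
        Rows sorted lexicographically by (anchor, partner); value +1 where
        expr(anchor) > expr(partner) in that sample, -1 otherwise (ties -1).
    """
    anchors = sorted(dict.fromkeys(anchor_genes))
    if not anchors:
        raise ValidationError("anchor gene set is empty")
    missing = [g for g in anchors if g not in expr.index]
    if partner_genes is None:
        partners = sorted(expr.index)
    else:
        partners = sorted(dict.fromkeys(partner_genes))
        missing += [g for g in partners if g not in expr.index]
    if missing:
        raise ValidationError(f"genes absent from expression matrix: {sorted(set(missing))}")

    pairs: list[tuple[str, str]] = []
    rows: list[np.ndarray] = []
    seen: set[frozenset] = set()
    mat = expr.to_numpy(dtype=float)
    gene_pos = {g: i for i, g in enumerate(expr.index)}
    for a in anchors:
        a_vals = mat[gene_pos[a]]
        for b in partners:
            if b == a:
                continue
            key = frozenset((a, b))
            if key in seen:
                continue
            seen.add(key)
            pairs.append((a, b))
            rows.append(np.where(a_vals > mat[gene_pos[b]], 1, -1).astype(np.int8))
    if not pairs:
        raise ValidationError("no pairs could be formed (partners all coincide with anchors)")
    values = np.vstack(rows)
    return GenePairMatrix(pairs=pairs, sample_ids=list(expr.columns), values=values)


def filter_pairs_by_frequency(
    gpm: GenePairMatrix,
    low: float = 0.20,
    high: float = 0.80,
) -> tuple[GenePairMatrix, pd.DataFrame]:
    """Drop near-constant pairs; keep those with +1 frequency in [low, high].

    Pairs coded +1 in more than ``high`` or fewer than ``low`` of samples
    carry little variability and are excluded; the bounds themselves are
    inclusive (a pair at exactly 20% or 80% is retained).

    Returns the filtered matrix and a report with one row per input pair
    (pair label, frequency, kept flag).  An empty result is permitted and
    raises only a warning.
    """
    if not (0 <= low < high <= 1):
        raise ValidationError(f"require 0 <= low < high <= 1, got low={low}, high={high}")
    freq = gpm.frequencies()
    keep = (freq >= low) & (freq <= high)
    report = pd.DataFrame(
        {"pair": gpm.pair_labels, "frequency": freq, "kept": keep}
    ).set_index("pair")
    if not keep.any():
        warnings.warn("frequency filter removed every pair", stacklevel=2)
        return (
            GenePairMatrix(pairs=[], sample_ids=list(gpm.sample_ids),
                           values=np.empty((0, len(gpm.sample_ids)), dtype=np.int8)),
            report,
        )
    kept_pairs = [p for p, k in zip(gpm.pairs, keep) if k]
    return (
        GenePairMatrix(pairs=kept_pairs, sample_ids=list(gpm.sample_ids),
                       values=gpm.values[keep]),
        report,
    )
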