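"""Tabular I/O: expression matrices, clinical tables, and fitted pair models.

Expression is tab-delimited genes x samples (first column = gene symbol,
header row = sample ids).  Clinical tables are comma- or tab-delimited with
named columns; the column mapping is configurable.  Fitted models are stored
as versioned JSON with full-precision coefficients.
"""

from __future__ import annotations

import json
import logging
import math

import numpy as np
import pandas as pd

from .errors import DataFormatError, ValidationError

__all__ = [
    "read_expression",
    "write_expression",
    "read_clinical",
    "write_clinical",
    "read_model",
    "write_model",
    "align_samples",
    "ISS_ALIASES",
]

logger = logging.getLogger(__name__)

MODEL_SCHEMA_VERSION = 1

#: Accepted spellings for ISS stages (case-insensitive after stripping).
ISS_ALIASES = {
    "1": 1, "2": 2, "3": 3,
    "i": 1, "ii": 2, "iii": 3,
    "stage 1": 1, "stage 2": 2, "stage 3": 3,
    "stage i": 1, "stage ii": 2, "stage iii": 3,
}

DEFAULT_CLINICAL_COLUMNS = {
    "sample_id": "sample_id",
    "os_time": "os_time",
    "os_event": "os_event",
    "iss": "iss",
    "age": "age",
    "gender": "gender",
}


def read_expression(path) -> pd.DataFrame:
    """Load a genes x samples expression TSV.

    Duplicate gene or sample ids, missing values, ragged rows and
    non-numeric cells are all hard errors — nothing is silently collapsed
    or imputed.
    """
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
    sample_ids = header[1:]
    dup_samples = pd.Index(sample_ids)[pd.Index(sample_ids).duplicated()].unique()
    if len(dup_samples):
        raise DataFormatError(f"duplicate sample ids: {list(dup_samples)}")
    try:
        df = pd.read_csv(path, sep="\t", index_col=0)
    except pd.errors.ParserError as exc:
        raise DataFormatError(f"malformed expression file {path}: {exc}") from exc
    dup_genes = df.index[df.index.duplicated()].unique()
    if len(dup_genes):
        raise DataFormatError(f"duplicate gene rows: {list(dup_genes)}")
    non_numeric = [c for c in df.columns if not pd.api.types.is_numeric_dtype(df[c])]
    if non_numeric:
        raise DataFormatError(f"non-numeric expression values in columns: {non_numeric}")
    if df.isna().any().any():
        bad = df.columns[df.isna().any()].tolist()
        raise DataFormatError(f"missing expression values (columns {bad})")
    if df.shape[0] < 2 or df.shape[1] < 2:
        raise DataFormatError(f"need at least 2 genes and 2 samples, got {df.shape}")
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    df.index.name = "gene"
    logger.info("read expression %s: %d genes x %d samples", path, *df.shape)
    return df.astype(float)


def write_expression(expr: pd.DataFrame, path) -> None:
    expr.to_csv(path, sep="\t", index_label="gene")
    logger.info("wrote expression %s: %d genes x %d samples", path, *expr.shape)


def _parse_iss(value):
    if pd.isna(value):
        return np.nan
    if isinstance(value, (int, np.integer)):
        iv = int(value)
    elif isinstance(value, float):
        if not value.is_integer():
            raise ValidationError(f"ISS stage must be integral, got {value}")
        iv = int(value)
    else:
        key = str(value).strip().lower()
        if key in ("", "na", "nan", "none", "-", "."):
            return np.nan
        if key not in ISS_ALIASES:
            raise ValidationError(f"unrecognized ISS stage {value!r}")
        iv = ISS_ALIASES[key]
    if iv not in (1, 2, 3):
        raise ValidationError(f"ISS stage out of range: {value!r}")
    return float(iv)


def read_clinical(path, column_map=None, sep=None) -> pd.DataFrame:
    """Load and validate a clinical table.

    Parameters
    ----------
    column_map
        Maps canonical names (sample_id, os_time, os_event, iss, age, gender)
        to the column names used in the file.  Optional columns missing from
        the file are filled with NaN.
    sep
        Field separator; sniffed (comma or tab) when None.

    Rows missing follow-up time or the event indicator are dropped with a
    logged report (count stored in ``df.attrs['n_dropped']``).  Invalid
    values — negative time, event outside {0,1}, ISS outside {1,2,3} — are
    errors that name the offending row.
    """
    colmap = dict(DEFAULT_CLINICAL_COLUMNS)
    if column_map:
        colmap.update(column_map)
    raw = pd.read_csv(path, sep=sep, engine="python" if sep is None else "c")
    for canon in ("sample_id", "os_time", "os_event"):
        if colmap[canon] not in raw.columns:
            raise DataFormatError(
                f"clinical file {path} lacks required column {colmap[canon]!r} ({canon})"
            )
    out = pd.DataFrame({"sample_id": raw[colmap["sample_id"]].astype(str)})
    out["os_time"] = pd.to_numeric(raw[colmap["os_time"]], errors="coerce")
    out["os_event"] = pd.to_numeric(raw[colmap["os_event"]], errors="coerce")
    for canon in ("iss", "age", "gender"):
        col = colmap[canon]
        out[canon] = raw[col] if col in raw.columns else np.nan

    incomplete = out["os_time"].isna() | out["os_event"].isna()
    n_dropped = int(incomplete.sum())
    if n_dropped:
        logger.warning(
            "dropping %d/%d clinical rows with missing os_time/os_event: %s",
            n_dropped, len(out), out.loc[incomplete, "sample_id"].tolist(),
        )
        out = out[~incomplete].copy()
    if out["sample_id"].duplicated().any():
        dups = out.loc[out["sample_id"].duplicated(), "sample_id"].unique()
        raise ValidationError(f"duplicate sample ids in clinical table: {list(dups)}")
    neg = out["os_time"] < 0
    if neg.any():
        raise ValidationError(
            f"negative os_time for samples {out.loc[neg, 'sample_id'].tolist()}"
        )
    bad_event = ~out["os_event"].isin([0, 1])
    if bad_event.any():
        raise ValidationError(
            f"os_event not in {{0,1}} for samples {out.loc[bad_event, 'sample_id'].tolist()}"
        )
    out["os_event"] = out["os_event"].astype(int)
    out["iss"] = out["iss"].map(_parse_iss)
    out["age"] = pd.to_numeric(out["age"], errors="coerce")
    if (out["age"] <= 0).any():
        bad = out.loc[out["age"] <= 0, "sample_id"].tolist()
        raise ValidationError(f"non-positive age for samples {bad}")
    out = out.set_index("sample_id")
    out.attrs["n_dropped"] = n_dropped
    logger.info("read clinical %s: %d samples (%d dropped)", path, len(out), n_dropped)
    return out


def write_clinical(clinical: pd.DataFrame, path, sep=",") -> None:
    clinical.to_csv(path, sep=sep, index_label="sample_id")


def write_model(model, path) -> None:
    """Serialize a fitted pair model to versioned JSON.

    Refuses structurally invalid models (empty pair list, duplicate pairs,
    zero/non-finite coefficients or cutoff).  Coefficients round-trip at full
    double precision.
    """
    pairs = list(model.pairs)
    coefs = np.asarray(model.coefficients, dtype=float)
    if len(pairs) == 0:
        raise ValidationError("refusing to write a model with no pairs")
    if len(pairs) != len(coefs):
        raise ValidationError("pairs and coefficients differ in length")
    seen = set()
    for a, b in pairs:
        if a == b:
            raise ValidationError(f"self-pair {a}|{b}")
        key = frozenset((a, b))
        if key in seen:
            raise ValidationError(f"duplicate pair {a}|{b}")
        seen.add(key)
    if not np.isfinite(coefs).all() or (coefs == 0).any():
        raise ValidationError("coefficients must be finite and nonzero")
    if not math.isfinite(float(model.risk_cutoff)):
        raise ValidationError("risk cutoff must be finite")
    payload = {
        "schema_version": MODEL_SCHEMA_VERSION,
        "model_type": "gene-pair-cox",
        "pairs": [
            {"anchor": a, "partner": b, "coefficient": float(c)}
            for (a, b), c in zip(pairs, coefs)
        ],
        "risk_cutoff": float(model.risk_cutoff),
        "provenance": dict(getattr(model, "provenance", {}) or {}),
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2)
        fh.write("\n")
    logger.info("wrote model %s: %d pairs, cutoff %g", path, len(pairs), model.risk_cutoff)


def read_model(path):
    """Load a pair model written by :func:`write_model`."""
    from .model import PairModel  # deferred: model builds on this module's siblings

    try:
        with open(path) as fh:
            payload = json.load(fh)
    except json.JSONDecodeError as exc:
        raise DataFormatError(f"malformed model file {path}: {exc}") from exc
    version = payload.get("schema_version")
    if version != MODEL_SCHEMA_VERSION:
        raise DataFormatError(
            f"model schema version mismatch: file has {version!r}, "
            f"expected {MODEL_SCHEMA_VERSION}"
        )
    pairs = [(p["anchor"], p["partner"]) for p in payload["pairs"]]
    coefs = np.array([p["coefficient"] for p in payload["pairs"]], dtype=float)
    model = PairModel(
        pairs=pairs,
        coefficients=coefs,
        risk_cutoff=float(payload["risk_cutoff"]),
        provenance=payload.get("provenance", {}),
    )
    logger.info("read model %s: %d pairs", path, len(pairs))
    return model


def align_samples(expr: pd.DataFrame, clinical: pd.DataFrame):
    """Restrict both tables to their shared samples, preserving expression order.

    Returns (expr, clinical, report) where report counts samples dropped
    from each side.
    """
    shared = [s for s in expr.columns if s in clinical.index]
    if not shared:
        raise ValidationError("expression and clinical tables share no samples")
    report = {
        "n_shared": len(shared),
        "n_expr_only": expr.shape[1] - len(shared),
        "n_clinical_only": len(clinical) - len(shared),
    }
    logger.info(
        "aligned samples: %(n_shared)d shared, %(n_expr_only)d expression-only, "
        "%(n_clinical_only)d clinical-only", report,
    )
    return expr[shared], clinical.loc[shared], report
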