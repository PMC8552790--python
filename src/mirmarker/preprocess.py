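"""Four-step expression preprocessing chain.

Order: missing-value filtering -> Z-score outlier handling with median
imputation -> SMOTE class balancing -> max-min normalisation.  Each step is
a pure function on :class:`ExpressionStudy`; :func:`run_preprocess` chains
the configured subset and logs record counts per stage.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .datatypes import ExpressionStudy, ValidationError

log = logging.getLogger(__name__)

ALL_STEPS = ("filter", "impute", "smote", "normalize")


@dataclass
class PreprocessConfig:
    """Tunable knobs of the preprocessing chain.

    max_missing_frac: rows whose missing fraction strictly exceeds this are
        dropped (default 0.2 — "more than 20%" is removed).
    z_thresh: per-row standard-score magnitude above which an entry is
        treated as an outlier and re-imputed (default 3.0).
    smote_k: nearest-neighbour count for minority oversampling (default 5).
    """

    max_missing_frac: float = 0.2
    z_thresh: float = 3.0
    smote_k: int = 5
    seed: int = 0
    steps: tuple[str, ...] = ALL_STEPS

    def __post_init__(self) -> None:
        if not (0.0 <= self.max_missing_frac <= 1.0):
            raise ValueError("max_missing_frac must be in [0, 1]")
        if self.z_thresh <= 0:
            raise ValueError("z_thresh must be > 0")
        if self.smote_k < 1:
            raise ValueError("smote_k must be >= 1")
        unknown = set(self.steps) - set(ALL_STEPS)
        if unknown:
            raise ValueError(f"unknown preprocessing steps: {sorted(unknown)}")


def filter_missing(study: ExpressionStudy, max_missing_frac: float = 0.2) -> ExpressionStudy:
    """Drop rows with a missing fraction strictly above ``max_missing_frac``.

    Surviving row order is preserved; dropping every row is a hard error.
    """
    frac = study.values.isna().mean(axis=1)
    keep = frac <= max_missing_frac
    if not keep.any():
        raise ValidationError("filter_missing would drop every row")
    out = study.copy()
    out.values = study.values.loc[keep].copy()
    return out


def impute(study: ExpressionStudy, z_thresh: float = 3.0) -> ExpressionStudy:
    """Mark per-row outliers (|standard score| > z_thresh, sample SD) as
    missing, then replace every missing entry with the row median over the
    remaining values.  A row with nothing left to take a median of is a
    hard error."""
    values = study.values.copy()
    arr = values.to_numpy(dtype=float)
    mean = np.nanmean(arr, axis=1, keepdims=True)
    sd = np.nanstd(arr, axis=1, ddof=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        z = np.abs(arr - mean) / sd
    arr = np.where(np.isfinite(z) & (z > z_thresh), np.nan, arr)
    all_missing = np.isnan(arr).all(axis=1)
    if all_missing.any():
        bad = values.index[all_missing].tolist()
        raise ValidationError(f"rows entirely missing after outlier removal: {bad[:5]}")
    med = np.nanmedian(arr, axis=1, keepdims=True)
    arr = np.where(np.isnan(arr), med, arr)
    out = study.copy()
    out.values = pd.DataFrame(arr, index=values.index, columns=values.columns)
    return out


def smote_balance(study: ExpressionStudy, k: int = 5, seed: int = 0) -> ExpressionStudy:
    """Balance class counts by SMOTE over the minority class.

    Each synthetic sample interpolates between a random minority sample and
    one of its k nearest minority neighbours (Euclidean distance over the
    per-sample expression vector) with a uniform weight in [0, 1].
    Synthetic samples get fresh IDs and the minority label; originals are
    untouched.  Deterministic given ``seed``.
    """
    if study.values.isna().any().any():
        raise ValidationError("SMOTE requires a fully imputed matrix (no missing entries)")
    counts = {lab: len(study.samples_with_label(lab)) for lab in ("tumor", "normal")}
    if min(counts.values()) == 0:
        raise ValidationError("both classes must be present for SMOTE")
    if counts["tumor"] == counts["normal"]:
        return study.copy()
    minority = min(counts, key=counts.get)
    n_min, n_maj = counts[minority], max(counts.values())
    if n_min < 2:
        raise ValidationError("minority class of size 1: SMOTE has no neighbours to interpolate")
    if k >= n_min:
        warnings.warn(f"smote_k={k} >= minority size {n_min}; clamping to {n_min - 1}")
        k = n_min - 1

    min_samples = study.samples_with_label(minority)
    X = study.values.loc[:, min_samples].to_numpy(dtype=float).T  # samples x features
    dist = cdist(X, X)
    np.fill_diagonal(dist, np.inf)
    neighbours = np.argsort(dist, axis=1, kind="stable")[:, :k]

    rng = np.random.default_rng(seed)
    n_new = n_maj - n_min
    base_idx = rng.integers(0, n_min, size=n_new)
    nbr_pick = rng.integers(0, k, size=n_new)
    weights = rng.random(n_new)
    synth = X[base_idx] + weights[:, None] * (X[neighbours[base_idx, nbr_pick]] - X[base_idx])

    new_ids = [f"{minority}_synthetic_{i + 1:04d}" for i in range(n_new)]
    new_cols = pd.DataFrame(synth.T, index=study.values.index, columns=new_ids)
    out_values = pd.concat([study.values, new_cols], axis=1)
    out_labels = pd.concat([study.labels, pd.Series(minority, index=new_ids)])
    return ExpressionStudy(
        values=out_values,
        labels=out_labels,
        pair_id=study.pair_id,
        provenance=study.provenance,
        synthetic_samples=study.synthetic_samples | frozenset(new_ids),
    )


def minmax_normalize(study: ExpressionStudy) -> ExpressionStudy:
    """Per-row max-min rescale to [0, 1]; constant rows map to zeros with a
    warning."""
    if study.values.isna().any().any():
        raise ValidationError("normalisation requires a fully imputed matrix")
    arr = study.values.to_numpy(dtype=float)
    lo = arr.min(axis=1, keepdims=True)
    hi = arr.max(axis=1, keepdims=True)
    span = hi - lo
    constant = (span == 0).ravel()
    if constant.any():
        warnings.warn(f"{int(constant.sum())} constant row(s) mapped to all-zeros")
    span = np.where(span == 0, 1.0, span)
    arr = (arr - lo) / span
    out = study.copy()
    out.values = pd.DataFrame(arr, index=study.values.index, columns=study.values.columns)
    return out


def run_preprocess(study: ExpressionStudy, config: PreprocessConfig | None = None) -> ExpressionStudy:
    """Apply the configured preprocessing steps in canonical order."""
    config = config or PreprocessConfig()
    out = study
    for step in ALL_STEPS:
        if step not in config.steps:
            continue
        n_rows, n_samples = out.values.shape
        if step == "filter":
            out = filter_missing(out, config.max_missing_frac)
        elif step == "impute":
            out = impute(out, config.z_thresh)
        elif step == "smote":
            out = smote_balance(out, config.smote_k, config.seed)
        elif step == "normalize":
            out = minmax_normalize(out)
        log.info(
            "preprocess %s: %d rows x %d samples -> %d rows x %d samples",
            step, n_rows, n_samples, *out.values.shape,
        )
    return out
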