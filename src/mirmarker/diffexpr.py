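"""Differential-expression screening: volcano thresholds, the
signal-to-noise separation score, and cross-dataset intersection.

The volcano stage screens each miRNA jointly on |log2 fold change| (tumor
over normal) and a two-group p-value; the SNR stage contrasts the class-mean
difference against the class spreads and discards low-scoring rows; the
intersection stage keeps miRNAs significant in every discovery dataset.
"""

from __future__ import annotations

import warnings
from typing import Iterable

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import ExpressionStudy, NORMAL, TUMOR

UP = "Up"
DOWN = "Down"
NOT_SIG = "NotSignificant"

DE_COLUMNS = ["log2fc", "pvalue", "snr", "status"]


def _class_matrices(study: ExpressionStudy) -> tuple[np.ndarray, np.ndarray]:
    t = study.values.loc[:, study.tumor_samples].to_numpy(dtype=float)
    n = study.values.loc[:, study.normal_samples].to_numpy(dtype=float)
    return t, n


def apply_status(table: pd.DataFrame, fc_thresh: float = 1.0, p_thresh: float = 0.05) -> pd.DataFrame:
    """(Re)derive the Up/Down/NotSignificant call from the thresholds."""
    out = table.copy()
    sig = out["pvalue"] < p_thresh
    out["status"] = NOT_SIG
    out.loc[sig & (out["log2fc"] >= fc_thresh), "status"] = UP
    out.loc[sig & (out["log2fc"] <= -fc_thresh), "status"] = DOWN
    return out


def volcano(
    study: ExpressionStudy,
    fc_thresh: float = 1.0,
    p_thresh: float = 0.05,
    test: str = "welch",
    *,
    eps: float = 1e-6,
) -> pd.DataFrame:
    """Per-miRNA log2 fold change, p-value and Up/Down call.

    log2FC = log2((mean tumor + eps) / (mean normal + eps)); the p-value
    comes from Welch's t on log2(x + eps) (default), a paired t aligned by
    pair ID, or the two-sided Wilcoxon rank-sum test.  Degenerate tests
    (zero variance) yield p = 1.
    """
    if not study.tumor_samples or not study.normal_samples:
        raise ValueError("both classes must be non-empty")
    if study.values.isna().any().any():
        raise ValueError("volcano requires a fully imputed matrix")
    t, n = _class_matrices(study)
    mean_t, mean_n = t.mean(axis=1), n.mean(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        log2fc = np.log2((mean_t + eps) / (mean_n + eps))

    log_t, log_n = np.log2(t + eps), np.log2(n + eps)
    if test == "welch":
        p = stats.ttest_ind(log_t, log_n, axis=1, equal_var=False).pvalue
    elif test == "paired_t":
        if study.pair_id is None:
            raise ValueError("paired_t requested but the study has no pairing IDs")
        pid = study.pair_id.dropna()
        keys = sorted(set(pid))
        t_cols, n_cols = [], []
        for key in keys:
            members = pid.index[pid == key]
            t_cols.append(next(s for s in members if study.labels[s] == TUMOR))
            n_cols.append(next(s for s in members if study.labels[s] == NORMAL))
        lt = np.log2(study.values.loc[:, t_cols].to_numpy(dtype=float) + eps)
        ln = np.log2(study.values.loc[:, n_cols].to_numpy(dtype=float) + eps)
        p = stats.ttest_rel(lt, ln, axis=1).pvalue
    elif test == "wilcoxon":
        p = np.array(
            [stats.mannwhitneyu(tr, nr, alternative="two-sided").pvalue for tr, nr in zip(t, n)]
        )
    else:
        raise ValueError(f"unknown test {test!r}")
    p = np.where(np.isnan(p), 1.0, p)

    table = pd.DataFrame({"log2fc": log2fc, "pvalue": p, "snr": np.nan}, index=study.values.index)
    return apply_status(table, fc_thresh, p_thresh)


def snr(study: ExpressionStudy, mode: str = "sum_abs") -> pd.Series:
    """Signal-to-noise separation score per miRNA.

    With u+/sigma+ the mean/SD over normal samples and u-/sigma- over tumor
    samples (sample SDs), ``sum_abs`` (default) scores
    |u+ - u-| / (sigma+ + sigma-); ``literal`` scores
    (u+ - u-) / (sigma+ - sigma-), which is sign-unstable and undefined
    (NaN, flagged) when the SDs coincide.
    """
    t, n = _class_matrices(study)
    if t.shape[1] < 2 or n.shape[1] < 2:
        raise ValueError("SNR needs at least 2 samples per class")
    u_pos, u_neg = n.mean(axis=1), t.mean(axis=1)
    s_pos = n.std(axis=1, ddof=1)
    s_neg = t.std(axis=1, ddof=1)
    if mode == "sum_abs":
        num = np.abs(u_pos - u_neg)
        den = s_pos + s_neg
        with np.errstate(divide="ignore", invalid="ignore"):
            score = np.where(den > 0, num / den, np.where(num > 0, np.inf, 0.0))
    elif mode == "literal":
        den = s_pos - s_neg
        with np.errstate(divide="ignore", invalid="ignore"):
            score = np.where(den != 0, (u_pos - u_neg) / den, np.nan)
        if np.isnan(score).any():
            warnings.warn(
                f"literal SNR undefined (equal class SDs) for {int(np.isnan(score).sum())} miRNA(s)"
            )
    else:
        raise ValueError(f"unknown SNR mode {mode!r}")
    return pd.Series(score, index=study.values.index, name="snr")


def snr_screen(de: pd.DataFrame, snr_min: float = 1.0) -> pd.DataFrame:
    """Keep rows whose SNR score is >= ``snr_min`` (ranking preserved)."""
    score = de["snr"]
    return de.loc[score >= snr_min].copy()


def sde_intersect(*sets: Iterable[str]) -> set[str]:
    """Intersection of per-dataset significant miRNA sets."""
    if not sets:
        return set()
    out = set(sets[0])
    for s in sets[1:]:
        out &= set(s)
    return out


def venn_membership(named_sets: dict[str, Iterable[str]]) -> pd.DataFrame:
    """Per-miRNA membership table across the named sets (Venn output)."""
    named = {k: set(v) for k, v in named_sets.items()}
    universe = sorted(set().union(*named.values())) if named else []
    return pd.DataFrame({k: [m in v for m in universe] for k, v in named.items()}, index=universe)


def de_mirnas(table: pd.DataFrame) -> set[str]:
    """IDs called Up or Down in a DE table."""
    return set(table.index[table["status"].isin([UP, DOWN])])
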