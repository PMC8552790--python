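"""ROC/AUC marker evaluation, candidate screening and the biomarker call.

AUC is the rank (Mann-Whitney) statistic: the probability that a random
tumor sample outranks a random normal sample, ties counted one half.  With
direction folding on, max(A, 1 - A) is reported together with the implied
direction, so down-regulated markers score on the same [0.5, 1] scale as
up-regulated ones.

A miRNA becomes a candidate when its (folded) AUC clears ``auc_min`` and
its NOG clears ``nog_min``; the top ``top_k`` by AUC survive.  A candidate
becomes a biomarker when some selected hub gene is independently regulated
by it and that gene sits in a declared disease-relevant pathway.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import ExpressionStudy, PathwayAnnotation, RegNetwork, TUMOR
from .regnet import independently_regulated_genes

UP_IN_TUMOR = "up-in-tumor"
DOWN_IN_TUMOR = "down-in-tumor"


def auc_rank(scores, labels, *, positive: str = TUMOR) -> float:
    """Raw AUC via the rank statistic U / (n1 * n2), ties counted 1/2."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    pos = scores[labels == positive]
    neg = scores[labels != positive]
    if pos.size == 0 or neg.size == 0:
        raise ValueError("both classes must be non-empty")
    ranks = stats.rankdata(np.concatenate([pos, neg]))
    u = ranks[: pos.size].sum() - pos.size * (pos.size + 1) / 2.0
    return float(u / (pos.size * neg.size))


def roc_points(scores, labels, *, positive: str = TUMOR) -> tuple[np.ndarray, np.ndarray]:
    """Empirical ROC curve (FPR, TPR) over all score thresholds."""
    scores = np.asarray(scores, dtype=float)
    y = (np.asarray(labels) == positive).astype(int)
    order = np.argsort(-scores, kind="stable")
    scores, y = scores[order], y[order]
    distinct = np.r_[np.diff(scores) != 0, True]
    tp = np.cumsum(y)[distinct]
    fp = np.cumsum(1 - y)[distinct]
    tpr = np.r_[0.0, tp / tp[-1]] if tp[-1] else np.r_[0.0, np.zeros(tp.size)]
    fpr = np.r_[0.0, fp / fp[-1]] if fp[-1] else np.r_[0.0, np.zeros(fp.size)]
    return fpr, tpr


def auc_trapezoid(scores, labels, *, positive: str = TUMOR) -> float:
    """AUC as the trapezoidal area under the empirical ROC curve (the
    internal cross-check for :func:`auc_rank`)."""
    fpr, tpr = roc_points(scores, labels, positive=positive)
    return float(np.trapezoid(tpr, fpr))


def auc(scores, labels, fold: bool = True, *, positive: str = TUMOR) -> tuple[float, str]:
    """(AUC, direction).  Folding reports max(A, 1 - A); constant scores
    give 0.5 with a warning."""
    scores = np.asarray(scores, dtype=float)
    if np.all(scores == scores[0]):
        warnings.warn("constant scores: AUC is 0.5 by convention")
    raw = auc_rank(scores, labels, positive=positive)
    direction = UP_IN_TUMOR if raw >= 0.5 else DOWN_IN_TUMOR
    return (max(raw, 1.0 - raw) if fold else raw), direction


def evaluate_markers(
    study: ExpressionStudy,
    mirnas=None,
    fold: bool = True,
) -> pd.DataFrame:
    """Per-miRNA AUC table (columns: auc, direction) using each miRNA's
    expression as the classifier score for tumor vs normal."""
    labels = np.asarray([study.labels[s] for s in study.samples])
    rows = list(mirnas) if mirnas is not None else study.mirnas
    missing = [m for m in rows if m not in study.values.index]
    if missing:
        raise KeyError(f"miRNAs absent from the study: {missing[:5]}")
    records = {}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for m in rows:
            a, d = auc(study.values.loc[m].to_numpy(), labels, fold=fold)
            records[m] = (a, d)
    return pd.DataFrame.from_dict(records, orient="index", columns=["auc", "direction"]).rename_axis("mirna")


def screen_candidates(
    eval_table: pd.DataFrame,
    nog_table: pd.DataFrame,
    auc_min: float = 0.9,
    nog_min: int = 3,
    top_k: int = 5,
) -> list[str]:
    """Candidate markers: AUC >= auc_min and NOG >= nog_min, ranked by AUC
    descending (ties: higher NOG, then lexicographic ID), truncated to
    ``top_k``."""
    shared = [m for m in eval_table.index if m in nog_table.index]
    df = pd.DataFrame(
        {
            "auc": eval_table.loc[shared, "auc"],
            "nog": nog_table.loc[shared, "nog"],
        }
    )
    df = df[(df["auc"] >= auc_min) & (df["nog"] >= nog_min)]
    df = df.assign(_id=df.index).sort_values(
        by=["auc", "nog", "_id"], ascending=[False, False, True], kind="stable"
    )
    out = list(df.index[: max(top_k, 0)])
    if not out:
        warnings.warn("no miRNA passed the candidate screen")
    return out


@dataclass(frozen=True)
class BiomarkerCall:
    """A candidate miRNA together with the hub gene it independently
    regulates and the relevant pathways supporting the call."""

    mirna: str
    hub_gene: str
    pathways: frozenset[str]
    auc: float = float("nan")
    nog: int = -1
    hub_degree: int = -1


def call_biomarkers(
    candidates,
    hubs,
    net: RegNetwork,
    ann: PathwayAnnotation,
    *,
    eval_table: pd.DataFrame | None = None,
    nog_table: pd.DataFrame | None = None,
    ppi=None,
) -> list[BiomarkerCall]:
    """Emit one call per (candidate miRNA, hub gene) pair where the hub is
    independently regulated by the candidate and annotated to at least one
    relevant pathway."""
    hubs = set(hubs)
    calls = []
    for m in candidates:
        if m not in net.mirnas:
            continue
        for g in sorted(independently_regulated_genes(net, m) & hubs):
            support = ann.relevant_pathways_of(g)
            if not support:
                continue
            calls.append(
                BiomarkerCall(
                    mirna=m,
                    hub_gene=g,
                    pathways=frozenset(support),
                    auc=float(eval_table.loc[m, "auc"]) if eval_table is not None and m in eval_table.index else float("nan"),
                    nog=int(nog_table.loc[m, "nog"]) if nog_table is not None and m in nog_table.index else -1,
                    hub_degree=int(ppi.graph.degree(g)) if ppi is not None and g in ppi.graph else -1,
                )
            )
    return calls


def calls_to_frame(calls: list[BiomarkerCall]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "mirna": c.mirna,
                "hub_gene": c.hub_gene,
                "pathways": ";".join(sorted(c.pathways)),
                "auc": c.auc,
                "nog": c.nog,
                "hub_degree": c.hub_degree,
            }
            for c in calls
        ],
        columns=["mirna", "hub_gene", "pathways", "auc", "nog", "hub_degree"],
    )


def paired_t(values_a, values_b) -> tuple[float, float]:
    """Classical paired t on aligned measurement vectors; zero-variance
    differences are flagged (NaN) rather than erroring."""
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.shape != b.shape or a.size < 2:
        raise ValueError("paired_t needs two aligned vectors of length >= 2")
    if np.std(a - b, ddof=1) == 0:
        warnings.warn("zero variance of paired differences: t undefined")
        return float("nan"), float("nan")
    res = stats.ttest_rel(a, b)
    return float(res.statistic), float(res.pvalue)


def pearson(x, y) -> tuple[float, float]:
    """Sample Pearson correlation with the t-transform p-value (n - 2 df);
    constant input is flagged (NaN) rather than erroring."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 3:
        raise ValueError("pearson needs two aligned vectors of length >= 3")
    if np.std(x) == 0 or np.std(y) == 0:
        warnings.warn("constant input: Pearson correlation undefined")
        return float("nan"), float("nan")
    res = stats.pearsonr(x, y)
    return float(res.statistic), float(res.pvalue)
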