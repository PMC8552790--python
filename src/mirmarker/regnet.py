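"""Independent-regulation statistics on the bipartite miRNA->gene network.

A gene with regulatory in-degree 1 is *independently regulated*: its sole
incoming edge makes the interaction fragile.  Per miRNA, NOG counts the
genes it uniquely targets.  The NOG distribution over a large merged
network is heavy-tailed; a log-log least-squares fit summarises it.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .datatypes import RegNetwork

NOG_COLUMNS = ["nog", "out_degree"]


def compute_nog(net: RegNetwork) -> pd.DataFrame:
    """NOG and out-degree per miRNA.

    nog(m) = number of genes whose only regulator is m.  The column sum of
    ``nog`` equals the number of genes with in-degree exactly 1.
    """
    nog: dict[str, int] = {m: 0 for m in net.mirnas}
    for g in net.genes:
        regs = net.regulators(g)
        if len(regs) == 1:
            nog[next(iter(regs))] += 1
    rows = sorted(nog)
    return pd.DataFrame(
        {"nog": [nog[m] for m in rows], "out_degree": [net.out_degree(m) for m in rows]},
        index=pd.Index(rows, name="mirna"),
    )


def independently_regulated_genes(net: RegNetwork, mirna: str) -> set[str]:
    """Genes whose only incoming regulatory edge comes from ``mirna``."""
    targets = net.targets(mirna)  # KeyError for unknown miRNA
    return {g for g in targets if net.in_degree(g) == 1}


def fit_power_law(values: np.ndarray | pd.Series) -> tuple[pd.Series, float]:
    """Histogram of positive integer values and a log-log least-squares
    slope over (value, frequency) pairs.

    Returns (histogram indexed by value >= 1, exponent).  The exponent is
    NaN when fewer than 3 distinct positive values exist.
    """
    vals = np.asarray(values, dtype=float)
    vals = vals[vals >= 1]
    if vals.size == 0:
        return pd.Series(dtype=int, name="count"), float("nan")
    uniq, counts = np.unique(vals.astype(int), return_counts=True)
    hist = pd.Series(counts, index=pd.Index(uniq, name="value"), name="count")
    if len(uniq) < 3:
        return hist, float("nan")
    slope = np.polyfit(np.log(uniq.astype(float)), np.log(counts.astype(float)), 1)[0]
    return hist, float(slope)


def nog_distribution(table: pd.DataFrame) -> tuple[pd.Series, float]:
    """Frequency of each NOG value >= 1 plus the fitted power-law exponent."""
    if table.empty:
        raise ValueError("empty NOG table")
    hist, exponent = fit_power_law(table["nog"])
    hist.index.name = "nog_value"
    return hist, exponent


def nog_summary(table: pd.DataFrame, strong_min: int = 3) -> dict[str, float]:
    """Headline fractions: share of miRNAs with any independent targets and
    with strong independent regulation (NOG >= ``strong_min``)."""
    n = len(table)
    return {
        "n_mirnas": n,
        "n_nog_ge1": int((table["nog"] >= 1).sum()),
        "frac_nog_ge1": float((table["nog"] >= 1).mean()) if n else float("nan"),
        "n_nog_strong": int((table["nog"] >= strong_min).sum()),
        "frac_nog_strong": float((table["nog"] >= strong_min).mean()) if n else float("nan"),
    }
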