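"""Readers and writers for the pipeline's tabular input formats.

Expression matrices travel as a delimited matrix file plus a sample sheet
(sample ID, label[, pair ID]).  Regulatory edges are two- or three-column
tables (miRNA, gene[, source]); PPI edges follow the STRING export layout
(protein1, protein2, combined_score), with the score either on the 0-1
probability scale or STRING's 0-1000 integer scale (auto-detected).
All writers emit the same dialects so every container round-trips.
"""

from __future__ import annotations

import warnings
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .datatypes import ExpressionStudy, PPIGraph, PathwayAnnotation, RegNetwork, ValidationError

MISSING_TOKENS = ["", "NA", "NaN", "nan", "na", "N/A"]


def _cell_to_float(x) -> float:
    """Exact (strtod) float parse; missing tokens and non-numeric text map
    to NaN.  Used instead of pandas' numeric coercion, whose parser is not
    bit-exact on round-trip."""
    s = str(x).strip()
    if s in MISSING_TOKENS:
        return np.nan
    try:
        return float(s)
    except ValueError:
        return np.nan


def _sep_for(path: str | Path, sep: str | None) -> str:
    if sep is not None:
        return sep
    return "," if str(path).endswith(".csv") else "\t"


def canonical_mirna(name: str) -> str:
    """miRBase-style names are case-insensitive in the wild: trim + lower-case."""
    return str(name).strip().lower()


def canonical_gene(name: str) -> str:
    """Gene symbols canonicalised to trimmed upper-case."""
    return str(name).strip().upper()


# ---------------------------------------------------------------------------
# expression matrices
# ---------------------------------------------------------------------------

def read_expression(
    matrix_path: str | Path,
    sample_sheet: str | Path | None = None,
    *,
    sep: str | None = None,
    transposed: bool = False,
    provenance: str = "",
) -> ExpressionStudy:
    """Read an expression matrix and its sample sheet into an ExpressionStudy.

    The matrix holds miRNAs on rows and samples on columns unless
    ``transposed`` is set.  Non-numeric cells become missing entries.
    Without a sample sheet every sample is labelled ``tumor`` (useful only
    for intermediate round-trips).
    """
    s = _sep_for(matrix_path, sep)
    df = pd.read_csv(matrix_path, sep=s, index_col=0, dtype=str, keep_default_na=False)
    if transposed:
        df = df.T
    if df.index.has_duplicates or df.columns.has_duplicates:
        raise ValidationError(f"duplicate IDs in {matrix_path}")
    values = df.apply(lambda col: col.map(_cell_to_float))
    if values.isna().all().all():
        raise ValidationError(f"{matrix_path}: matrix is entirely missing/non-numeric")

    if sample_sheet is not None:
        sheet = pd.read_csv(sample_sheet, sep=_sep_for(sample_sheet, sep), dtype=str)
        sheet.columns = [c.strip().lower() for c in sheet.columns]
        sheet = sheet.set_index(sheet.columns[0])
        labels = sheet.iloc[:, 0].str.strip().str.lower()
        pair_id = None
        if sheet.shape[1] >= 2:
            raw = sheet.iloc[:, 1].replace(MISSING_TOKENS, np.nan)
            if raw.notna().any():
                pair_id = raw
    else:
        labels = pd.Series("tumor", index=values.columns)
        pair_id = None
    return ExpressionStudy(values=values, labels=labels, pair_id=pair_id, provenance=provenance or str(matrix_path))


def write_expression(
    study: ExpressionStudy,
    matrix_path: str | Path,
    sample_sheet: str | Path | None = None,
    *,
    sep: str | None = None,
) -> None:
    s = _sep_for(matrix_path, sep)
    study.values.to_csv(matrix_path, sep=s, na_rep="NA")
    if sample_sheet is not None:
        sheet = pd.DataFrame({"sample": study.samples})
        sheet["label"] = [study.labels[x] for x in study.samples]
        if study.pair_id is not None:
            sheet["pair"] = [study.pair_id.get(x, np.nan) for x in study.samples]
        sheet.to_csv(sample_sheet, sep=_sep_for(sample_sheet, sep), index=False, na_rep="NA")


# ---------------------------------------------------------------------------
# regulatory edge lists
# ---------------------------------------------------------------------------

def _read_table_flexible(path: str | Path, expected: Sequence[str], sep: str | None) -> pd.DataFrame:
    """Read a delimited table; accept either a header naming ``expected``
    columns (case-insensitive, any order) or a headerless positional file."""
    s = _sep_for(path, sep)
    df = pd.read_csv(path, sep=s, dtype=str, header=None, keep_default_na=False)
    first = [str(x).strip().lower() for x in df.iloc[0]]
    if any(name in first for name in expected):
        df.columns = first
        df = df.iloc[1:].reset_index(drop=True)
        cols = []
        for name in expected:
            cols.append(name if name in first else None)
        out = pd.DataFrame()
        for i, name in enumerate(expected):
            if cols[i] is not None:
                out[name] = df[cols[i]]
            elif i < df.shape[1] and df.columns[i] not in expected:
                out[name] = df.iloc[:, i]
        return out
    df = df.iloc[:, : len(expected)]
    df.columns = list(expected)[: df.shape[1]]
    return df


def read_edge_lists(
    paths: Iterable[str | Path],
    *,
    sep: str | None = None,
    case_fold: bool = True,
) -> RegNetwork:
    """Union of miRNA->gene edge lists with merged per-edge source sets.

    IDs are canonicalised (trimmed; miRNAs lower-cased, genes upper-cased
    when ``case_fold``).  Files without a ``source`` column contribute their
    file stem as the source name.  The result is independent of file order.
    """
    edges: dict[tuple[str, str], set[str]] = {}
    for path in paths:
        df = _read_table_flexible(path, ["mirna", "gene", "source"], sep)
        default_src = Path(path).stem
        has_source = "source" in df.columns and df["source"].astype(str).str.strip().ne("").any()
        for _, row in df.iterrows():
            m, g = str(row["mirna"]).strip(), str(row["gene"]).strip()
            if not m or not g:
                continue
            if case_fold:
                m, g = canonical_mirna(m), canonical_gene(g)
            src = str(row.get("source", "")).strip() if has_source else ""
            edges.setdefault((m, g), set()).add(src or default_src)
    if not edges:
        raise ValidationError("edge-list union is empty")
    return RegNetwork(edges={k: frozenset(v) for k, v in edges.items()})


def write_edge_list(net: RegNetwork, path: str | Path, *, sep: str | None = None) -> None:
    s = _sep_for(path, sep)
    rows = [
        {"mirna": m, "gene": g, "source": ";".join(sorted(srcs))}
        for (m, g), srcs in sorted(net.edges.items())
    ]
    pd.DataFrame(rows, columns=["mirna", "gene", "source"]).to_csv(path, sep=s, index=False)


# ---------------------------------------------------------------------------
# PPI graphs
# ---------------------------------------------------------------------------

def read_ppi(
    path: str | Path,
    min_score: float = 0.9,
    *,
    sep: str | None = None,
    scale: str = "auto",
    case_fold: bool = True,
) -> PPIGraph:
    """Read a STRING-style PPI export, keeping edges with score strictly
    above ``min_score`` (on the 0-1 probability scale).

    ``scale`` is ``"auto"`` (any score > 1 implies the 0-1000 integer
    scale), ``"unit"`` or ``"milli"``.  A score outside both recognised
    scales is a hard error naming the offending row.
    """
    df = _read_table_flexible(path, ["protein1", "protein2", "combined_score"], sep)
    if "combined_score" not in df.columns:
        raise ValidationError(f"{path}: no combined_score column found")
    scores = df["combined_score"].map(_cell_to_float)
    if scores.isna().any():
        bad = int(scores.index[scores.isna()][0])
        raise ValidationError(f"{path} row {bad}: non-numeric combined score")
    if (scores < 0).any() or (scores > 1000).any():
        bad = int(scores.index[(scores < 0) | (scores > 1000)][0])
        raise ValidationError(
            f"{path} row {bad}: score {scores.iloc[bad]} outside both the 0-1 and 0-1000 scales"
        )
    if scale == "auto":
        scale = "milli" if (scores > 1).any() else "unit"
    if scale == "milli":
        scores = scores / 1000.0
    elif scale != "unit":
        raise ValueError(f"unknown scale {scale!r}")

    edges: dict[frozenset, float] = {}
    n_loops = 0
    for (_, row), score in zip(df.iterrows(), scores):
        u, v = str(row["protein1"]).strip(), str(row["protein2"]).strip()
        if case_fold:
            u, v = canonical_gene(u), canonical_gene(v)
        if u == v:
            n_loops += 1
            continue
        if score > min_score:
            key = frozenset((u, v))
            edges[key] = max(edges.get(key, 0.0), float(score))
    if n_loops:
        warnings.warn(f"{path}: dropped {n_loops} self-loop(s)")
    g = PPIGraph.from_edges((tuple(sorted(k)) + (s,) for k, s in edges.items()))
    return g


def write_ppi(ppi: PPIGraph, path: str | Path, *, sep: str | None = None) -> None:
    s = _sep_for(path, sep)
    rows = [
        {"protein1": min(u, v), "protein2": max(u, v), "combined_score": repr(d.get("score", 1.0))}
        for u, v, d in ppi.graph.edges(data=True)
    ]
    rows.sort(key=lambda r: (r["protein1"], r["protein2"]))
    pd.DataFrame(rows, columns=["protein1", "protein2", "combined_score"]).to_csv(path, sep=s, index=False)


# ---------------------------------------------------------------------------
# pathway annotations
# ---------------------------------------------------------------------------

def read_pathways(
    path: str | Path,
    relevant: Iterable[str] | str | Path = (),
    *,
    sep: str | None = None,
    case_fold: bool = True,
) -> PathwayAnnotation:
    """Read a gene -> pathway TSV; ``relevant`` is an iterable of pathway
    IDs or a path to a one-ID-per-line file."""
    df = _read_table_flexible(path, ["gene", "pathway"], sep)
    assignments: dict[str, set[str]] = {}
    for _, row in df.iterrows():
        g, p = str(row["gene"]).strip(), str(row["pathway"]).strip()
        if not g or not p:
            continue
        if case_fold:
            g = canonical_gene(g)
        assignments.setdefault(g, set()).add(p)
    if isinstance(relevant, (str, Path)):
        relevant = [ln.strip() for ln in Path(relevant).read_text().splitlines() if ln.strip()]
    ann = PathwayAnnotation(assignments=assignments, relevant=set(relevant))
    if ann.absent_relevant:
        warnings.warn(f"relevant pathway IDs absent from annotation: {sorted(ann.absent_relevant)}")
    return ann


def write_pathways(ann: PathwayAnnotation, path: str | Path, *, sep: str | None = None) -> None:
    s = _sep_for(path, sep)
    rows = [
        {"gene": g, "pathway": p}
        for g in sorted(ann.assignments)
        for p in sorted(ann.assignments[g])
    ]
    pd.DataFrame(rows, columns=["gene", "pathway"]).to_csv(path, sep=s, index=False)
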