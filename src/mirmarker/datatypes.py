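"""Core in-memory containers for the screening pipeline.

Four objects travel through the pipeline: an expression study (miRNA x
sample matrix with tumor/normal labels and optional tumor-normal pairing),
a unidirectional miRNA->gene regulatory network, an undirected
protein-protein interaction graph with edge confidence scores, and a
gene->pathway annotation with a declared set of disease-relevant pathways.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import networkx as nx
import numpy as np
import pandas as pd

TUMOR = "tumor"
NORMAL = "normal"
VALID_LABELS = frozenset({TUMOR, NORMAL})


class ValidationError(ValueError):
    """Raised when a container violates one of its structural invariants."""


@dataclass
class ExpressionStudy:
    """Expression matrix (rows = miRNA IDs, columns = sample IDs).

    Missing measurements are represented as NaN.  ``labels`` assigns every
    sample to ``tumor`` or ``normal``; ``pair_id`` optionally links each
    tumor sample to its paraneoplastic (matched normal) sample via a shared
    key.  ``synthetic_samples`` records sample IDs created by oversampling
    so downstream statistics can exclude them on request.
    """

    values: pd.DataFrame
    labels: pd.Series
    pair_id: pd.Series | None = None
    provenance: str = ""
    synthetic_samples: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        self.values = self.values.astype(float)
        self.labels = self.labels.astype(str)
        self.validate()

    def validate(self) -> None:
        idx = self.values.index
        cols = self.values.columns
        if idx.has_duplicates:
            dup = idx[idx.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate miRNA IDs: {dup[:5]}")
        if cols.has_duplicates:
            dup = cols[cols.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate sample IDs: {dup[:5]}")
        missing = set(cols) - set(self.labels.index)
        if missing:
            raise ValidationError(f"samples without a label: {sorted(missing)[:5]}")
        bad = set(self.labels.loc[list(cols)]) - VALID_LABELS
        if bad:
            raise ValidationError(f"labels must be in {sorted(VALID_LABELS)}, got {sorted(bad)}")
        if self.values.size and self.values.isna().all().all():
            raise ValidationError("expression matrix is entirely missing")
        if self.pair_id is not None:
            pid = self.pair_id.dropna()
            for key, samples in pid.groupby(pid).groups.items():
                labs = sorted(self.labels.loc[list(samples)])
                if labs != [NORMAL, TUMOR]:
                    raise ValidationError(
                        f"pair {key!r} must map to exactly one tumor and one normal sample, got {labs}"
                    )

    # -- convenience -----------------------------------------------------
    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)

    @property
    def mirnas(self) -> list[str]:
        return list(self.values.index)

    def samples_with_label(self, label: str) -> list[str]:
        return [s for s in self.values.columns if self.labels[s] == label]

    @property
    def tumor_samples(self) -> list[str]:
        return self.samples_with_label(TUMOR)

    @property
    def normal_samples(self) -> list[str]:
        return self.samples_with_label(NORMAL)

    def subset_samples(self, samples: Iterable[str]) -> "ExpressionStudy":
        samples = list(samples)
        pid = self.pair_id.loc[[s for s in samples if s in self.pair_id.index]] if self.pair_id is not None else None
        return ExpressionStudy(
            values=self.values.loc[:, samples].copy(),
            labels=self.labels.loc[samples].copy(),
            pair_id=pid,
            provenance=self.provenance,
            synthetic_samples=frozenset(s for s in self.synthetic_samples if s in samples),
        )

    def drop_synthetic(self) -> "ExpressionStudy":
        return self.subset_samples([s for s in self.samples if s not in self.synthetic_samples])

    def copy(self) -> "ExpressionStudy":
        return ExpressionStudy(
            values=self.values.copy(),
            labels=self.labels.copy(),
            pair_id=None if self.pair_id is None else self.pair_id.copy(),
            provenance=self.provenance,
            synthetic_samples=self.synthetic_samples,
        )

    def equals(self, other: "ExpressionStudy") -> bool:
        same_pid = (
            (self.pair_id is None and other.pair_id is None)
            or (self.pair_id is not None and other.pair_id is not None and self.pair_id.equals(other.pair_id))
        )
        return self.values.equals(other.values) and self.labels.equals(other.labels) and same_pid


@dataclass
class RegNetwork:
    """Unidirectional miRNA -> gene regulatory network.

    ``edges`` maps each (miRNA, gene) pair to the set of source databases
    that reported it; duplicate pairs across sources are merged.
    """

    edges: dict[tuple[str, str], frozenset[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.edges = {pair: frozenset(src) for pair, src in self.edges.items()}
        self._targets: dict[str, set[str]] = {}
        self._regulators: dict[str, set[str]] = {}
        for (m, g) in self.edges:
            self._targets.setdefault(m, set()).add(g)
            self._regulators.setdefault(g, set()).add(m)

    @property
    def mirnas(self) -> set[str]:
        return set(self._targets)

    @property
    def genes(self) -> set[str]:
        return set(self._regulators)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def targets(self, mirna: str) -> set[str]:
        if mirna not in self._targets:
            raise KeyError(f"unknown miRNA {mirna!r}")
        return set(self._targets[mirna])

    def regulators(self, gene: str) -> set[str]:
        if gene not in self._regulators:
            raise KeyError(f"unknown gene {gene!r}")
        return set(self._regulators[gene])

    def in_degree(self, gene: str) -> int:
        return len(self._regulators.get(gene, ()))

    def out_degree(self, mirna: str) -> int:
        return len(self._targets.get(mirna, ()))

    def __eq__(self, other: object) -> bool:
        return isinstance(other, RegNetwork) and self.edges == other.edges


@dataclass
class PPIGraph:
    """Undirected protein-protein interaction graph.

    Edge confidence lives in the ``score`` attribute, normalised to [0, 1]
    (the probability-of-interaction scale).  Self-loops and duplicate edges
    are invalid.
    """

    graph: nx.Graph

    def __post_init__(self) -> None:
        loops = list(nx.selfloop_edges(self.graph))
        if loops:
            raise ValidationError(f"PPI graph contains self-loops: {loops[:5]}")
        for u, v, d in self.graph.edges(data=True):
            s = d.get("score", 1.0)
            if not (0.0 <= s <= 1.0):
                raise ValidationError(f"edge ({u}, {v}) score {s} outside [0, 1]")

    @classmethod
    def from_edges(cls, edges: Iterable[tuple[str, str, float]]) -> "PPIGraph":
        g = nx.Graph()
        for u, v, s in edges:
            g.add_edge(u, v, score=float(s))
        return cls(g)

    @property
    def nodes(self) -> set[str]:
        return set(self.graph.nodes)

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def subgraph(self, nodes: Iterable[str]) -> "PPIGraph":
        return PPIGraph(self.graph.subgraph(set(nodes)).copy())

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, PPIGraph):
            return NotImplemented
        if set(self.graph.nodes) != set(other.graph.nodes):
            return False
        mine = {frozenset((u, v)): d.get("score") for u, v, d in self.graph.edges(data=True)}
        theirs = {frozenset((u, v)): d.get("score") for u, v, d in other.graph.edges(data=True)}
        return mine == theirs


@dataclass
class PathwayAnnotation:
    """Gene -> pathway assignments plus the declared disease-relevant set."""

    assignments: dict[str, set[str]] = field(default_factory=dict)
    relevant: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        self.assignments = {g: set(p) for g, p in self.assignments.items()}
        self.relevant = set(self.relevant)
        all_pathways = set().union(*self.assignments.values()) if self.assignments else set()
        self._absent_relevant = self.relevant - all_pathways

    @property
    def absent_relevant(self) -> set[str]:
        """Relevant pathway IDs no annotated gene belongs to (flagged, not an error)."""
        return set(self._absent_relevant)

    def pathways_of(self, gene: str) -> set[str]:
        return set(self.assignments.get(gene, ()))

    def relevant_pathways_of(self, gene: str) -> set[str]:
        return self.pathways_of(gene) & self.relevant
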