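"""Nine node-centrality measures for PPI hub scoring, plus the
upper-quartile-in-all-methods hub selector.

Definitions (frozen here so divergence from other tools is auditable):

- Degree(v): neighbour count.
- MNC(v): order of the largest connected component of the subgraph induced
  by N(v), v excluded; 0 for an isolated node.
- DMNC(v): |E(C)| / |V(C)|**eps over that same component C (eps = 1.7);
  0 when C has no edges.  Ties in component order break toward more edges.
- MCC(v): sum over maximal cliques C containing v with |C| >= 2 of
  (|C| - 1)!; isolated nodes score 0.
- Betweenness(v): sum over unordered pairs {s, t}, s != v != t, of
  sigma_st(v) / sigma_st (shortest-path fractions).
- Stress(v): same sum of raw shortest-path counts sigma_st(v).
- Closeness(v): harmonic, sum over t != v of 1 / d(v, t); unreachable t
  contributes 0 (finite on disconnected graphs).
- Radiality(v): sum over reachable t != v of (diam + 1 - d(v, t)) divided
  by (|comp| - 1), with diam the diameter of v's component; singleton
  components score 0.
- EPC(v): Monte-Carlo edge percolation.  Each iteration draws a keep
  probability p ~ U[0, 1], retains each edge independently with
  probability p, and counts the nodes still connected to v; the score is
  the mean count divided by n.  Deterministic given the seed.
"""

from __future__ import annotations

from collections import deque
from math import factorial

import networkx as nx
import numpy as np
import pandas as pd

from .datatypes import PPIGraph

METHODS = (
    "MCC",
    "DMNC",
    "MNC",
    "Degree",
    "EPC",
    "Closeness",
    "Radiality",
    "Betweenness",
    "Stress",
)

DMNC_EPSILON = 1.7


def _as_graph(g: PPIGraph | nx.Graph) -> nx.Graph:
    return g.graph if isinstance(g, PPIGraph) else g


def _bfs_counts(adj: dict, s) -> tuple[dict, dict, list, dict]:
    """Single-source BFS: distances, shortest-path counts, a reverse
    processing order, and predecessor lists (Brandes machinery)."""
    dist = {s: 0}
    sigma = {s: 1.0}
    preds: dict = {s: []}
    order = []
    q = deque([s])
    while q:
        v = q.popleft()
        order.append(v)
        for w in adj[v]:
            if w not in dist:
                dist[w] = dist[v] + 1
                sigma[w] = 0.0
                preds[w] = []
                q.append(w)
            if dist[w] == dist[v] + 1:
                sigma[w] += sigma[v]
                preds[w].append(v)
    return dist, sigma, order, preds


def betweenness_and_stress(g: PPIGraph | nx.Graph) -> tuple[dict, dict]:
    """Brandes-style accumulation of betweenness and stress over unordered
    node pairs."""
    G = _as_graph(g)
    adj = {v: list(G.neighbors(v)) for v in G}
    bet = {v: 0.0 for v in G}
    stress = {v: 0.0 for v in G}
    for s in G:
        dist, sigma, order, preds = _bfs_counts(adj, s)
        delta_b = {v: 0.0 for v in order}
        delta_s = {v: 0.0 for v in order}
        for w in reversed(order):
            for v in preds[w]:
                frac = sigma[v] / sigma[w]
                delta_b[v] += frac * (1.0 + delta_b[w])
                delta_s[v] += sigma[v] + frac * delta_s[w]
            if w != s:
                bet[w] += delta_b[w]
                stress[w] += delta_s[w]
    # every unordered pair was visited from both endpoints
    return {v: b / 2.0 for v, b in bet.items()}, {v: x / 2.0 for v, x in stress.items()}


def harmonic_closeness(g: PPIGraph | nx.Graph) -> dict:
    G = _as_graph(g)
    adj = {v: list(G.neighbors(v)) for v in G}
    out = {}
    for v in G:
        dist, _, _, _ = _bfs_counts(adj, v)
        out[v] = sum(1.0 / d for u, d in dist.items() if u != v)
    return out


def radiality(g: PPIGraph | nx.Graph) -> dict:
    G = _as_graph(g)
    out = {v: 0.0 for v in G}
    adj = {v: list(G.neighbors(v)) for v in G}
    for comp in nx.connected_components(G):
        comp = list(comp)
        if len(comp) == 1:
            continue
        dists = {}
        diam = 0
        for v in comp:
            dist, _, _, _ = _bfs_counts(adj, v)
            dists[v] = dist
            diam = max(diam, max(dist.values()))
        for v in comp:
            out[v] = sum(diam + 1 - d for u, d in dists[v].items() if u != v) / (len(comp) - 1)
    return out


def mnc_dmnc(g: PPIGraph | nx.Graph, eps: float = DMNC_EPSILON) -> tuple[dict, dict]:
    G = _as_graph(g)
    mnc, dmnc = {}, {}
    for v in G:
        nbrs = list(G.neighbors(v))
        if not nbrs:
            mnc[v], dmnc[v] = 0.0, 0.0
            continue
        sub = G.subgraph(nbrs)
        best = max(
            (sub.subgraph(c) for c in nx.connected_components(sub)),
            key=lambda c: (c.number_of_nodes(), c.number_of_edges()),
        )
        mnc[v] = float(best.number_of_nodes())
        e = best.number_of_edges()
        dmnc[v] = e / best.number_of_nodes() ** eps if e > 0 else 0.0
    return mnc, dmnc


def mcc(g: PPIGraph | nx.Graph) -> dict:
    G = _as_graph(g)
    out = {v: 0.0 for v in G}
    for clique in nx.find_cliques(G):
        if len(clique) < 2:
            continue
        w = float(factorial(len(clique) - 1))
        for v in clique:
            out[v] += w
    return out


def epc(g: PPIGraph | nx.Graph, iters: int = 100, seed: int = 0) -> dict:
    """Monte-Carlo edge-percolated component score (see module docstring)."""
    G = _as_graph(g)
    nodes = list(G.nodes)
    n = len(nodes)
    idx = {v: i for i, v in enumerate(nodes)}
    edges = np.array([(idx[u], idx[v]) for u, v in G.edges], dtype=np.int64).reshape(-1, 2)
    rng = np.random.default_rng(seed)
    totals = np.zeros(n)
    parent = np.empty(n, dtype=np.int64)

    def find(x: int) -> int:
        root = x
        while parent[root] != root:
            root = parent[root]
        while parent[x] != root:
            parent[x], x = root, parent[x]
        return root

    for _ in range(iters):
        p = rng.random()
        keep = rng.random(len(edges)) < p
        parent[:] = np.arange(n)
        for a, b in edges[keep]:
            ra, rb = find(a), find(b)
            if ra != rb:
                parent[rb] = ra
        roots = np.array([find(i) for i in range(n)])
        _, inverse, counts = np.unique(roots, return_inverse=True, return_counts=True)
        totals += counts[inverse] - 1  # nodes connected to v, excluding v
    return {v: totals[idx[v]] / iters / n for v in nodes}


def compute_centralities(
    g: PPIGraph | nx.Graph,
    methods: tuple[str, ...] | None = None,
    epc_iters: int = 100,
    seed: int = 0,
    *,
    dmnc_eps: float = DMNC_EPSILON,
) -> pd.DataFrame:
    """Node x method score table over the PPI graph.

    Topology-only: edge confidence scores are ignored.  An empty graph is a
    hard error.
    """
    G = _as_graph(g)
    if G.number_of_nodes() == 0:
        raise ValueError("empty graph")
    methods = tuple(methods) if methods is not None else METHODS
    unknown = set(methods) - set(METHODS)
    if unknown:
        raise ValueError(f"unknown centrality methods: {sorted(unknown)}")

    cols: dict[str, dict] = {}
    if "Degree" in methods:
        cols["Degree"] = {v: float(d) for v, d in G.degree()}
    if "MNC" in methods or "DMNC" in methods:
        mnc_scores, dmnc_scores = mnc_dmnc(G, dmnc_eps)
        cols["MNC"], cols["DMNC"] = mnc_scores, dmnc_scores
    if "MCC" in methods:
        cols["MCC"] = mcc(G)
    if "Betweenness" in methods or "Stress" in methods:
        bet, stress = betweenness_and_stress(G)
        cols["Betweenness"], cols["Stress"] = bet, stress
    if "Closeness" in methods:
        cols["Closeness"] = harmonic_closeness(G)
    if "Radiality" in methods:
        cols["Radiality"] = radiality(G)
    if "EPC" in methods:
        cols["EPC"] = epc(G, iters=epc_iters, seed=seed)

    nodes = sorted(G.nodes, key=str)
    table = pd.DataFrame({m: [cols[m][v] for v in nodes] for m in methods}, index=pd.Index(nodes, name="node"))
    return table


def select_hubs(table: pd.DataFrame, quantile: float = 0.75) -> set:
    """Nodes scoring strictly above the per-method quantile (linear
    interpolation) in every method of the table."""
    if len(table) < 4:
        raise ValueError("hub selection needs at least 4 nodes for a quartile")
    thresholds = table.quantile(quantile, interpolation="linear")
    mask = (table > thresholds).all(axis=1)
    return set(table.index[mask])
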