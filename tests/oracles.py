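"""Independent brute-force oracles used to verify the package's network
statistics.  Everything here is computed by naive enumeration (all simple
paths, all vertex subsets) and deliberately shares no code with the
implementation under test."""

from __future__ import annotations

from itertools import combinations
from math import factorial, inf


def all_simple_paths(adj: dict, s, t) -> list[list]:
    """Every simple s-t path, by DFS."""
    out: list[list] = []

    def dfs(v, path, seen):
        if v == t:
            out.append(path[:])
            return
        for w in adj[v]:
            if w not in seen:
                seen.add(w)
                path.append(w)
                dfs(w, path, seen)
                path.pop()
                seen.remove(w)

    dfs(s, [s], {s})
    return out


def shortest_path_info(adj: dict, s, t):
    """(distance, shortest path list) by exhaustive simple-path enumeration."""
    paths = all_simple_paths(adj, s, t)
    if not paths:
        return inf, []
    d = min(len(p) - 1 for p in paths)
    return d, [p for p in paths if len(p) - 1 == d]


def _adj(G) -> dict:
    return {v: sorted(G.neighbors(v), key=str) for v in G}


def _components(nodes, edgeset):
    nodes = list(nodes)
    seen, comps = set(), []
    adj = {v: set() for v in nodes}
    for u, v in edgeset:
        if u in adj and v in adj:
            adj[u].add(v)
            adj[v].add(u)
    for v in nodes:
        if v in seen:
            continue
        comp, stack = set(), [v]
        while stack:
            x = stack.pop()
            if x in comp:
                continue
            comp.add(x)
            stack.extend(adj[x] - comp)
        seen |= comp
        comps.append(comp)
    return comps


def brute_centralities(G, dmnc_eps: float = 1.7) -> dict[str, dict]:
    """The eight deterministic centrality measures by exhaustive enumeration."""
    adj = _adj(G)
    nodes = list(G.nodes)
    edges = {frozenset(e) for e in G.edges}

    # all-pairs shortest paths by simple-path enumeration
    dist: dict[tuple, float] = {}
    spaths: dict[tuple, list] = {}
    for s, t in combinations(nodes, 2):
        d, paths = shortest_path_info(adj, s, t)
        dist[(s, t)] = dist[(t, s)] = d
        spaths[(s, t)] = paths

    bet = {v: 0.0 for v in nodes}
    stress = {v: 0.0 for v in nodes}
    for (s, t), paths in spaths.items():
        if not paths:
            continue
        for v in nodes:
            if v in (s, t):
                continue
            through = sum(1 for p in paths if v in p)
            if through:
                bet[v] += through / len(paths)
                stress[v] += through

    closeness = {
        v: sum(1.0 / dist[(v, t)] for t in nodes if t != v and dist[(v, t)] < inf)
        for v in nodes
    }

    radial = {v: 0.0 for v in nodes}
    for comp in _components(nodes, edges):
        if len(comp) == 1:
            continue
        diam = max(dist[(s, t)] for s, t in combinations(sorted(comp, key=str), 2))
        for v in comp:
            radial[v] = sum(diam + 1 - dist[(v, t)] for t in comp if t != v) / (len(comp) - 1)

    degree = {v: float(len(adj[v])) for v in nodes}

    mnc, dmnc = {}, {}
    for v in nodes:
        nbrs = adj[v]
        if not nbrs:
            mnc[v], dmnc[v] = 0.0, 0.0
            continue
        comps = _components(nbrs, edges)
        best = max(comps, key=lambda c: (len(c), sum(1 for e in edges if e <= c)))
        e_in = sum(1 for e in edges if e <= best)
        mnc[v] = float(len(best))
        dmnc[v] = e_in / len(best) ** dmnc_eps if e_in else 0.0

    # maximal cliques by subset enumeration
    def is_clique(sub):
        return all(frozenset((a, b)) in edges for a, b in combinations(sub, 2))

    cliques = [set(sub) for r in range(2, len(nodes) + 1) for sub in combinations(nodes, r) if is_clique(sub)]
    maximal = [c for c in cliques if not any(c < d for d in cliques)]
    mcc = {v: 0.0 for v in nodes}
    for c in maximal:
        w = float(factorial(len(c) - 1))
        for v in c:
            mcc[v] += w

    return {
        "Degree": degree,
        "MNC": mnc,
        "DMNC": dmnc,
        "MCC": mcc,
        "Betweenness": bet,
        "Stress": stress,
        "Closeness": closeness,
        "Radiality": radial,
    }


def epc_exact_moments(G, v) -> tuple[float, float]:
    """Exact first and second moments of the per-iteration EPC summand for
    node ``v``: each iteration keeps each edge with probability p ~ U[0, 1]
    (drawn once), and the summand is (#nodes still connected to v) / n.
    Computed by enumerating every edge subset with its Beta-integral
    weight."""
    edges = list(G.edges)
    nodes = list(G.nodes)
    n, m = len(nodes), len(edges)
    e1 = e2 = 0.0
    for r in range(m + 1):
        w = factorial(r) * factorial(m - r) / factorial(m + 1)  # integral of p^r (1-p)^(m-r)
        for keep in combinations(range(m), r):
            sub = {frozenset(edges[i]) for i in keep}
            comp = next(c for c in _components(nodes, sub) if v in c)
            x = (len(comp) - 1) / n
            e1 += w * x
            e2 += w * x * x
    return e1, e2


def brute_nog(edges: list[tuple[str, str]]) -> dict[str, int]:
    """NOG per miRNA by direct in-degree inspection of a (miRNA, gene)
    edge list."""
    mirnas = {m for m, _ in edges}
    genes = {g for _, g in edges}
    nog = {m: 0 for m in mirnas}
    for g in genes:
        regs = {m for m, gg in set(edges) if gg == g}
        if len(regs) == 1:
            nog[next(iter(regs))] += 1
    return nog
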