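"""Fully synthetic inputs with the statistical structure the screening
pipeline assumes.

Expression matrices are paired tumor/normal log-normal measurements with a
planted differentially expressed subset; regulatory networks are bipartite
with power-law miRNA out-degrees and planted uniquely-targeted genes; PPI
graphs are preferential-attachment backbones with planted hub cliques;
pathway tables are sparse random assignments with a guaranteed relevant
pathway for the planted gene.  Every generator is bit-reproducible given
its seed, and each returns the ground truth it planted so recovery can be
scored.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .datatypes import ExpressionStudy, PPIGraph, PathwayAnnotation, RegNetwork


@dataclass
class GroundTruth:
    """What a generator planted, for recovery scoring."""

    de_up: dict[str, float] = field(default_factory=dict)
    de_down: dict[str, float] = field(default_factory=dict)
    unique_targets: dict[str, set[str]] = field(default_factory=dict)
    planted_hubs: tuple[str, ...] = ()
    planted_biomarker: tuple[str, str, str] | None = None

    @property
    def de_mirnas(self) -> set[str]:
        return set(self.de_up) | set(self.de_down)

    def merge(self, other: "GroundTruth") -> "GroundTruth":
        return GroundTruth(
            de_up={**self.de_up, **other.de_up},
            de_down={**self.de_down, **other.de_down},
            unique_targets={**self.unique_targets, **other.unique_targets},
            planted_hubs=self.planted_hubs + other.planted_hubs,
            planted_biomarker=self.planted_biomarker or other.planted_biomarker,
        )


def _child_seeds(seed: int, n: int) -> list[int]:
    """Derive independent integer sub-seeds from one master seed."""
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    return [int(s) for s in rng.integers(0, 2**31 - 1, size=n)]


# ---------------------------------------------------------------------------
# expression
# ---------------------------------------------------------------------------

def generate_expression(
    n_pairs: int = 40,
    n_mirnas: int = 300,
    n_de: int = 10,
    effect_log2: float = 3.0,
    noise_sd: float = 0.5,
    missing_frac: float = 0.0,
    seed: int = 0,
    *,
    mirna_ids: Sequence[str] | None = None,
    de_ids: Sequence[str] | None = None,
    pair_effect_sd: float = 0.3,
    provenance: str = "synthetic",
) -> tuple[ExpressionStudy, GroundTruth]:
    """Paired tumor/normal expression with a planted DE subset.

    Measurements are log-normal: per-miRNA baselines uniform on [4, 10] in
    log2 units, a shared per-pair random effect, and Gaussian log2 noise of
    SD ``noise_sd``.  The first half of the planted set is shifted up by
    ``effect_log2`` in tumor samples, the rest down.  Missing entries are
    sprinkled independently at rate ``missing_frac``.
    """
    if n_pairs < 3:
        raise ValueError("n_pairs must be >= 3")
    if n_de > n_mirnas:
        raise ValueError("n_de must be <= n_mirnas")
    if not (0.0 <= missing_frac < 1.0):
        raise ValueError("missing_frac must be in [0, 1)")
    rng = np.random.default_rng(seed)
    mirnas = list(mirna_ids) if mirna_ids is not None else [f"mir{i + 1:04d}" for i in range(n_mirnas)]
    if len(mirnas) != n_mirnas:
        raise ValueError("mirna_ids length must equal n_mirnas")
    if de_ids is not None:
        de = list(de_ids)
        if len(de) != n_de or set(de) - set(mirnas):
            raise ValueError("de_ids must be n_de IDs drawn from mirna_ids")
    else:
        de = [mirnas[i] for i in rng.choice(n_mirnas, size=n_de, replace=False)]
    n_up = (n_de + 1) // 2
    up, down = de[:n_up], de[n_up:]

    baseline = rng.uniform(4.0, 10.0, size=n_mirnas)
    pair_eff = rng.normal(0.0, pair_effect_sd, size=n_pairs)
    shift = np.zeros(n_mirnas)
    idx = {m: i for i, m in enumerate(mirnas)}
    for m in up:
        shift[idx[m]] = effect_log2
    for m in down:
        shift[idx[m]] = -effect_log2

    cols, labels, pairs = [], {}, {}
    data = np.empty((n_mirnas, 2 * n_pairs))
    for j in range(n_pairs):
        for k, lab in enumerate(("tumor", "normal")):
            sid = f"P{j + 1:03d}{'T' if lab == 'tumor' else 'N'}"
            log2x = baseline + pair_eff[j] + rng.normal(0.0, noise_sd, size=n_mirnas)
            if lab == "tumor":
                log2x = log2x + shift
            data[:, 2 * j + k] = 2.0 ** log2x
            cols.append(sid)
            labels[sid] = lab
            pairs[sid] = f"P{j + 1:03d}"
    if missing_frac > 0:
        mask = rng.random(data.shape) < missing_frac
        data = np.where(mask, np.nan, data)

    study = ExpressionStudy(
        values=pd.DataFrame(data, index=mirnas, columns=cols),
        labels=pd.Series(labels),
        pair_id=pd.Series(pairs),
        provenance=provenance,
    )
    truth = GroundTruth(
        de_up={m: effect_log2 for m in up},
        de_down={m: -effect_log2 for m in down},
    )
    return study, truth


# ---------------------------------------------------------------------------
# regulatory network
# ---------------------------------------------------------------------------

def generate_regnet(
    n_mirnas: int = 200,
    n_genes: int = 800,
    exponent: float = -2.0,
    planted: Iterable[tuple[str, int]] = (),
    seed: int = 0,
    *,
    mirna_ids: Sequence[str] | None = None,
    gene_prefix: str = "GENE",
    max_out: int = 50,
    enforce_min_indegree: bool = True,
) -> tuple[RegNetwork, GroundTruth]:
    """Bipartite miRNA->gene network with power-law out-degrees and planted
    uniquely-targeted genes.

    Each planted (miRNA, count) pair reserves ``count`` fresh genes wired
    with in-degree exactly 1 from that miRNA.  Remaining genes are targeted
    by miRNAs whose out-degrees follow P(k) proportional to k**exponent,
    then (by default) topped up so every non-reserved gene has at least two
    regulators — the planted NOG values are exact by construction.
    """
    planted = list(planted)
    rng = np.random.default_rng(seed)
    mirnas = list(mirna_ids) if mirna_ids is not None else [f"mir{i + 1:04d}" for i in range(n_mirnas)]
    for m, _ in planted:
        if m not in mirnas:
            raise ValueError(f"planted miRNA {m!r} not among the generated IDs")
    n_reserved = sum(c for _, c in planted)
    if n_reserved > n_genes:
        raise ValueError("infeasible planting: reserved unique targets exceed n_genes")
    genes = [f"{gene_prefix}{i + 1:05d}" for i in range(n_genes)]
    reserved_iter = iter(genes[:n_reserved])
    pool = genes[n_reserved:]
    if len(pool) < 2 and enforce_min_indegree and pool:
        raise ValueError("too few free genes to guarantee co-regulation")

    edges: dict[tuple[str, str], set[str]] = {}
    truth = GroundTruth()
    for m, count in planted:
        mine = {next(reserved_iter) for _ in range(count)}
        truth.unique_targets[m] = mine
        for g in mine:
            edges[(m, g)] = {"synthetic"}

    ks = np.arange(1, max_out + 1)
    pk = ks.astype(float) ** exponent
    pk /= pk.sum()
    out_deg = rng.choice(ks, size=len(mirnas), p=pk)
    for m, d in zip(mirnas, out_deg):
        if not pool:
            break
        chosen = rng.choice(len(pool), size=min(d, len(pool)), replace=False)
        for gi in chosen:
            edges[(m, pool[gi])] = {"synthetic"}

    if enforce_min_indegree and pool:
        indeg: dict[str, set[str]] = {g: set() for g in pool}
        for (m, g) in edges:
            if g in indeg:
                indeg[g].add(m)
        for g, regs in indeg.items():
            need = 2 - len(regs)
            if need <= 0:
                continue
            others = [m for m in mirnas if m not in regs]
            for mi in rng.choice(len(others), size=need, replace=False):
                edges[(others[mi], g)] = {"synthetic"}

    net = RegNetwork(edges={k: frozenset(v) for k, v in edges.items()})
    return net, truth


# ---------------------------------------------------------------------------
# PPI
# ---------------------------------------------------------------------------

def generate_ppi(
    n_genes: int = 250,
    attach_m: int = 2,
    planted_hubs: Iterable[str] = (),
    clique_size: int = 8,
    seed: int = 0,
    *,
    gene_ids: Sequence[str] | None = None,
    extra_attach: int = 12,
    score_low: float = 0.905,
) -> tuple[PPIGraph, GroundTruth]:
    """Scale-free PPI backbone with planted hub genes.

    The backbone is preferential attachment (``attach_m`` edges per new
    node).  Each planted hub is embedded in a clique of ``clique_size``
    nodes and given ``extra_attach`` additional random attachments, pushing
    it above the upper quartile on degree-like and clique-based measures.
    All edge confidence scores are drawn strictly above 0.9.
    """
    planted_hubs = list(planted_hubs)
    if clique_size < 3:
        raise ValueError("clique_size must be >= 3")
    rng = np.random.default_rng(seed)
    backbone = nx.barabasi_albert_graph(n_genes, attach_m, seed=int(rng.integers(2**31 - 1)))
    ids = list(gene_ids) if gene_ids is not None else [f"GENE{i + 1:05d}" for i in range(n_genes)]
    if len(ids) != n_genes:
        raise ValueError("gene_ids length must equal n_genes")
    # shuffle the backbone-node -> ID assignment so planted hubs start as
    # ordinary nodes (their prominence must come from the planted clique,
    # not from landing on an early preferential-attachment node)
    perm = rng.permutation(n_genes)
    g = nx.relabel_nodes(backbone, {i: ids[perm[i]] for i in range(n_genes)})
    for h in planted_hubs:
        if h not in g:
            raise ValueError(f"planted hub {h!r} not among the graph's gene IDs")
        others = [x for x in ids if x != h and x not in planted_hubs]
        members = [h] + [others[i] for i in rng.choice(len(others), size=clique_size - 1, replace=False)]
        for i, u in enumerate(members):
            for v in members[i + 1 :]:
                g.add_edge(u, v)
        spare = [x for x in ids if x != h and not g.has_edge(h, x)]
        for i in rng.choice(len(spare), size=min(extra_attach, len(spare)), replace=False):
            g.add_edge(h, spare[i])
    for u, v in g.edges:
        g.edges[u, v]["score"] = float(rng.uniform(score_low, 1.0))
    return PPIGraph(g), GroundTruth(planted_hubs=tuple(planted_hubs))


# ---------------------------------------------------------------------------
# pathways
# ---------------------------------------------------------------------------

def generate_pathways(
    genes: Iterable[str],
    n_pathways: int = 10,
    relevant: Iterable[str] = ("PW0001",),
    planted_gene: str | None = None,
    seed: int = 0,
    *,
    background_relevant: bool = False,
    assign_prob: float = 0.6,
    max_per_gene: int = 2,
) -> PathwayAnnotation:
    """Sparse random gene->pathway assignment.

    The planted gene is guaranteed membership in a relevant pathway.  By
    default background genes draw only from non-relevant pathways (disease
    pathway membership is sparse); set ``background_relevant`` to let them
    leak into the relevant set too.
    """
    genes = sorted(set(genes))
    relevant = sorted(set(relevant))
    if planted_gene is not None and planted_gene not in genes:
        raise ValueError(f"planted gene {planted_gene!r} not in the gene set")
    universe = sorted(set(f"PW{i + 1:04d}" for i in range(n_pathways)) | set(relevant))
    background = universe if background_relevant else [p for p in universe if p not in relevant]
    rng = np.random.default_rng(seed)
    assignments: dict[str, set[str]] = {}
    for gidx, gene in enumerate(genes):
        if background and rng.random() < assign_prob:
            k = int(rng.integers(1, max_per_gene + 1))
            picks = rng.choice(len(background), size=min(k, len(background)), replace=False)
            assignments[gene] = {background[i] for i in picks}
    if planted_gene is not None:
        assignments.setdefault(planted_gene, set()).add(relevant[0])
    return PathwayAnnotation(assignments=assignments, relevant=set(relevant))


# ---------------------------------------------------------------------------
# coherent end-to-end bundle
# ---------------------------------------------------------------------------

@dataclass
class SyntheticBundle:
    """All four pipeline inputs plus the combined ground truth."""

    studies: list[ExpressionStudy]
    net: RegNetwork
    ppi: PPIGraph
    ann: PathwayAnnotation
    truth: GroundTruth


def generate_bundle(
    seed: int = 0,
    *,
    planted: bool = True,
    n_pairs: int = 40,
    n_mirnas: int = 300,
    n_de: int = 10,
    effect_log2: float = 3.0,
    noise_sd: float = 0.5,
    missing_frac: float = 0.02,
    n_reg_genes: int = 600,
    n_ppi_genes: int = 250,
    clique_size: int = 8,
) -> SyntheticBundle:
    """A coherent study scenario for the full pipeline.

    With ``planted`` on, one up-regulated DE miRNA (the designated marker)
    uniquely targets four genes, one of which is embedded as a PPI hub and
    annotated to a relevant pathway; two other DE miRNAs act as decoys with
    NOG = 3 but no relevant-pathway hub.  The pipeline should recover
    exactly the planted (miRNA, hub gene, pathway) triple.  With ``planted``
    off (the null), no differential expression or unique targeting is
    planted and zero biomarker calls are expected.
    """
    seeds = _child_seeds(seed, 8)
    master = np.random.default_rng(seeds[0])
    mirnas = [f"mir{i + 1:04d}" for i in range(n_mirnas)]

    if planted:
        de_ids = [mirnas[i] for i in master.choice(n_mirnas, size=n_de, replace=False)]
    else:
        n_de, effect_log2, de_ids = 0, 0.0, []
    study_a, truth_a = generate_expression(
        n_pairs, n_mirnas, n_de, effect_log2, noise_sd, missing_frac,
        seed=seeds[1], mirna_ids=mirnas, de_ids=de_ids, provenance="synthetic-discovery-A",
    )
    study_b, _ = generate_expression(
        max(3, int(0.75 * n_pairs)), n_mirnas, n_de, effect_log2, noise_sd, missing_frac,
        seed=seeds[2], mirna_ids=mirnas, de_ids=de_ids, provenance="synthetic-discovery-B",
    )

    if planted:
        marker = de_ids[0]  # an up-shifted DE miRNA by construction
        decoys = de_ids[1:3]
        planted_reg = [(marker, 4)] + [(d, 3) for d in decoys]
    else:
        marker, decoys, planted_reg = None, [], []
    net, truth_net = generate_regnet(
        n_mirnas, n_reg_genes, exponent=-2.0, planted=planted_reg,
        seed=seeds[3], mirna_ids=mirnas,
    )

    reserved = sorted(set().union(*truth_net.unique_targets.values())) if truth_net.unique_targets else []
    other_genes = [go for go in sorted(net.genes) if go not in reserved]
    n_fill = n_ppi_genes - len(reserved)
    fill = [other_genes[i] for i in master.choice(len(other_genes), size=n_fill, replace=False)]
    ppi_genes = reserved + fill
    hub_gene = sorted(truth_net.unique_targets[marker])[0] if planted else None
    ppi, truth_ppi = generate_ppi(
        n_ppi_genes, attach_m=2,
        planted_hubs=[hub_gene] if hub_gene else [],
        clique_size=clique_size, seed=seeds[4], gene_ids=ppi_genes,
    )

    ann = generate_pathways(
        ppi_genes, n_pathways=10, relevant=("PW0001",),
        planted_gene=hub_gene, seed=seeds[5],
    )

    truth = truth_a.merge(truth_net).merge(truth_ppi)
    if planted:
        truth.planted_biomarker = (marker, hub_gene, "PW0001")
    return SyntheticBundle(studies=[study_a, study_b], net=net, ppi=ppi, ann=ann, truth=truth)


def write_bundle(bundle: SyntheticBundle, outdir) -> dict[str, str]:
    """Write the bundle's four inputs (plus a ground-truth manifest) as the
    pipeline's TSV dialects; returns the path map."""
    from pathlib import Path

    from . import io as mio

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, str] = {}
    for i, study in enumerate(bundle.studies):
        tag = chr(ord("a") + i)
        m, s = out / f"expression_{tag}.tsv", out / f"samples_{tag}.tsv"
        mio.write_expression(study, m, s)
        paths[f"expression_{tag}"] = str(m)
        paths[f"samples_{tag}"] = str(s)
    mio.write_edge_list(bundle.net, out / "regnet.tsv")
    paths["regnet"] = str(out / "regnet.tsv")
    mio.write_ppi(bundle.ppi, out / "ppi.tsv")
    paths["ppi"] = str(out / "ppi.tsv")
    mio.write_pathways(bundle.ann, out / "pathways.tsv")
    paths["pathways"] = str(out / "pathways.tsv")
    (out / "relevant_pathways.txt").write_text("\n".join(sorted(bundle.ann.relevant)) + "\n")
    paths["relevant"] = str(out / "relevant_pathways.txt")

    t = bundle.truth
    manifest = pd.DataFrame(
        [
            {"kind": "de_up", "key": m, "value": v} for m, v in sorted(t.de_up.items())
        ]
        + [{"kind": "de_down", "key": m, "value": v} for m, v in sorted(t.de_down.items())]
        + [
            {"kind": "unique_target", "key": m, "value": g}
            for m, gs in sorted(t.unique_targets.items())
            for g in sorted(gs)
        ]
        + [{"kind": "planted_hub", "key": h, "value": ""} for h in t.planted_hubs]
        + (
            [{"kind": "planted_biomarker", "key": t.planted_biomarker[0], "value": f"{t.planted_biomarker[1]};{t.planted_biomarker[2]}"}]
            if t.planted_biomarker
            else []
        ),
        columns=["kind", "key", "value"],
    )
    manifest.to_csv(out / "ground_truth.tsv", sep="\t", index=False)
    paths["ground_truth"] = str(out / "ground_truth.tsv")
    return paths
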