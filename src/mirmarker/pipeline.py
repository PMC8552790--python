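"""End-to-end orchestration: preprocess -> differential expression per
discovery dataset -> intersection -> NOG -> AUC -> candidate screen -> PPI
hub consensus -> biomarker call.

The PPI input is expected to be an export already restricted to the
target-gene universe of interest (as a STRING export of candidate-target
genes is); hub centralities are computed on the graph as given.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import pandas as pd
import yaml

from . import io as mio
from .datatypes import ExpressionStudy, PPIGraph, PathwayAnnotation, RegNetwork
from .preprocess import PreprocessConfig, filter_missing, impute, minmax_normalize, smote_balance
from .diffexpr import apply_status, de_mirnas, sde_intersect, snr, snr_screen, volcano
from .regnet import compute_nog
from .centrality import compute_centralities, select_hubs
from .screen import BiomarkerCall, call_biomarkers, calls_to_frame, evaluate_markers, screen_candidates


@dataclass
class RunConfig:
    """Every tunable of the pipeline, with defaults frozen to the published
    screening thresholds: drop rows missing in more than 20% of samples,
    |log2FC| >= 1, p < 0.05, SNR >= 1, AUC >= 0.9, top 5, NOG >= 3, PPI
    combined score > 0.9, hub quantile 0.75."""

    # preprocessing
    max_missing_frac: float = 0.2
    z_thresh: float = 3.0
    smote_k: int = 5
    # differential expression
    fc_thresh: float = 1.0
    p_thresh: float = 0.05
    de_test: str = "welch"
    snr_mode: str = "sum_abs"
    snr_min: float = 1.0
    exclude_synthetic_from_de: bool = False
    # screening
    auc_min: float = 0.9
    nog_min: int = 3
    top_k: int = 5
    # PPI / hubs
    ppi_min_score: float = 0.9
    hub_quantile: float = 0.75
    epc_iters: int = 100
    # bookkeeping
    seed: int = 0
    outdir: str | None = None
    # input paths (used by the CLI `run` subcommand)
    expression: list[dict] = field(default_factory=list)  # [{matrix:, samples:}, ...]
    regnet: list[str] = field(default_factory=list)
    ppi: str | None = None
    pathways: str | None = None
    relevant: list[str] | str = field(default_factory=list)

    def __post_init__(self) -> None:
        checks = [
            (0.0 <= self.max_missing_frac <= 1.0, "max_missing_frac in [0, 1]"),
            (self.z_thresh > 0, "z_thresh > 0"),
            (self.smote_k >= 1, "smote_k >= 1"),
            (self.fc_thresh >= 0, "fc_thresh >= 0"),
            (0.0 < self.p_thresh <= 1.0, "p_thresh in (0, 1]"),
            (0.0 <= self.auc_min <= 1.0, "auc_min in [0, 1]"),
            (self.nog_min >= 0, "nog_min >= 0"),
            (self.top_k >= 0, "top_k >= 0"),
            (0.0 <= self.ppi_min_score <= 1.0, "ppi_min_score in [0, 1]"),
            (0.0 < self.hub_quantile < 1.0, "hub_quantile in (0, 1)"),
            (self.epc_iters >= 1, "epc_iters >= 1"),
        ]
        for ok, msg in checks:
            if not ok:
                raise ValueError(f"config violates {msg}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))


@dataclass
class PipelineResult:
    """Everything the run produced, stage by stage."""

    de_tables: list[pd.DataFrame]
    sde: set[str]
    nog_table: pd.DataFrame
    eval_table: pd.DataFrame
    candidates: list[str]
    centrality_table: pd.DataFrame
    hubs: set[str]
    calls: list[BiomarkerCall]
    log: list[str]

    def write(self, outdir: str | Path) -> None:
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        for i, table in enumerate(self.de_tables):
            table.rename_axis("mirna").to_csv(out / f"de_dataset_{chr(ord('a') + i)}.tsv", sep="\t")
        (out / "sde_mirnas.txt").write_text("".join(f"{m}\n" for m in sorted(self.sde)))
        self.nog_table.to_csv(out / "nog.tsv", sep="\t")
        self.eval_table.to_csv(out / "auc.tsv", sep="\t")
        (out / "candidates.txt").write_text("".join(f"{m}\n" for m in self.candidates))
        self.centrality_table.to_csv(out / "centrality.tsv", sep="\t")
        (out / "hub_genes.txt").write_text("".join(f"{g}\n" for g in sorted(self.hubs)))
        calls_to_frame(self.calls).to_csv(out / "biomarkers.tsv", sep="\t", index=False)
        (out / "run_log.txt").write_text("".join(f"{line}\n" for line in self.log))


def preprocess_study(study: ExpressionStudy, config: RunConfig, *, normalize: bool = False) -> ExpressionStudy:
    """filter -> impute -> SMOTE (and optionally max-min normalise)."""
    out = filter_missing(study, config.max_missing_frac)
    out = impute(out, config.z_thresh)
    out = smote_balance(out, config.smote_k, config.seed)
    if normalize:
        out = minmax_normalize(out)
    return out


def run_pipeline(
    studies: Sequence[ExpressionStudy],
    net: RegNetwork,
    ppi: PPIGraph,
    ann: PathwayAnnotation,
    config: RunConfig | None = None,
) -> PipelineResult:
    """Execute the full screen over in-memory inputs.

    Differential statistics are computed on the imputed, pre-normalisation
    matrix (max-min rescaling destroys fold-change meaning; AUC is
    rank-based and unaffected).  Deterministic given ``config.seed``.
    """
    config = config or RunConfig()
    if not studies:
        raise ValueError("at least one discovery study is required")
    log: list[str] = [f"config: seed={config.seed}"]

    # stage 1-2: preprocessing + per-dataset differential expression
    de_tables: list[pd.DataFrame] = []
    sde_sets: list[set[str]] = []
    processed: list[ExpressionStudy] = []
    for i, raw in enumerate(studies):
        study = preprocess_study(raw, config)
        processed.append(study)
        log.append(
            f"dataset {i}: {raw.values.shape[0]} miRNAs x {raw.values.shape[1]} samples "
            f"-> {study.values.shape[0]} x {study.values.shape[1]} after preprocessing"
        )
        de_input = study.drop_synthetic() if config.exclude_synthetic_from_de else study
        table = volcano(de_input, config.fc_thresh, config.p_thresh, config.de_test)
        table["snr"] = snr(de_input, config.snr_mode)
        n_volcano = len(de_mirnas(table))
        screened = snr_screen(table, config.snr_min)
        screened = apply_status(screened, config.fc_thresh, config.p_thresh)
        sde_i = de_mirnas(screened)
        log.append(
            f"dataset {i}: {n_volcano} volcano-significant, "
            f"{len(screened)}/{len(table)} pass SNR >= {config.snr_min}, {len(sde_i)} SDE"
        )
        de_tables.append(table)
        sde_sets.append(sde_i)

    sde = sde_intersect(*sde_sets)
    log.append(f"intersection: {len(sde)} SDE miRNAs across {len(sde_sets)} datasets")

    # stage 3: NOG on the regulatory network
    nog_table = compute_nog(net)
    log.append(f"regulatory network: {len(net.mirnas)} miRNAs, {len(net.genes)} genes, {net.n_edges} edges")

    # stage 4: AUC on the first discovery dataset
    evaluable = sorted(m for m in sde if m in processed[0].values.index)
    if evaluable:
        eval_table = evaluate_markers(processed[0], evaluable, fold=True)
    else:
        eval_table = pd.DataFrame(columns=["auc", "direction"]).rename_axis("mirna")
    log.append(f"AUC evaluated for {len(eval_table)} SDE miRNAs")

    # stage 5: candidate screen
    candidates = screen_candidates(
        eval_table, nog_table, config.auc_min, config.nog_min, config.top_k
    ) if len(eval_table) else []
    log.append(f"candidates (AUC >= {config.auc_min}, NOG >= {config.nog_min}, top {config.top_k}): {candidates}")

    # stage 6: hub consensus on the PPI
    centrality_table = compute_centralities(ppi, epc_iters=config.epc_iters, seed=config.seed)
    hubs = select_hubs(centrality_table, config.hub_quantile)
    log.append(f"PPI: {ppi.n_nodes} nodes, {ppi.n_edges} edges; {len(hubs)} hub genes above Q{int(config.hub_quantile * 100)}")

    # stage 7: biomarker call
    calls = call_biomarkers(
        candidates, hubs, net, ann,
        eval_table=eval_table, nog_table=nog_table, ppi=ppi,
    )
    log.append(f"biomarker calls: {[(c.mirna, c.hub_gene) for c in calls]}")

    result = PipelineResult(
        de_tables=de_tables,
        sde=sde,
        nog_table=nog_table,
        eval_table=eval_table,
        candidates=candidates,
        centrality_table=centrality_table,
        hubs=hubs,
        calls=calls,
        log=log,
    )
    if config.outdir:
        result.write(config.outdir)
    return result


def run_from_config(config: RunConfig) -> PipelineResult:
    """Load the configured input files and run the pipeline."""
    studies = [
        mio.read_expression(spec["matrix"], spec.get("samples"))
        for spec in config.expression
    ]
    net = mio.read_edge_lists(config.regnet)
    ppi = mio.read_ppi(config.ppi, config.ppi_min_score)
    ann = mio.read_pathways(config.pathways, config.relevant)
    return run_pipeline(studies, net, ppi, ann, config)
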