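# Methods

## Overview

`mirmarker` screens miRNA biomarkers by combining three orthogonal kinds of
evidence: expression (differential expression and diagnostic AUC), network
position (independent regulation of hub genes), and pathway context. The
pipeline is deterministic given its seed and every stage is a pure function
over explicit containers (expression study, regulatory network, PPI graph,
pathway annotation), so stages can be run, audited and tested in isolation.

## Preprocessing

Four steps, in fixed order, each configurable and skippable:

- **Missing-value filter.** A miRNA row is dropped when its missing
  fraction strictly exceeds `max_missing_frac` (default 0.2, i.e. rows
  missing in *more than* 20 % of samples go; exactly 20 % stays).
- **Outlier handling + imputation.** Per row, entries with sample-SD
  standard score |z| > `z_thresh` (default 3.0) are marked missing, then
  all missing entries are replaced by the row median over the surviving
  values. The same median rule serves outliers and original gaps. A row
  with nothing left to take a median of is a hard error.
- **SMOTE balancing.** Tumor/normal cohorts from tissue archives are
  heavily imbalanced. Synthetic minority samples interpolate between a
  random minority sample and one of its `smote_k` (default 5, the
  conventional choice) nearest minority neighbours under Euclidean
  distance over the per-sample expression vector, with a uniform weight in
  [0, 1]. Synthetic samples carry fresh IDs, the minority label and no
  pairing key; they are tracked so downstream statistics can exclude them
  (`exclude_synthetic_from_de`, default off to match the stated pipeline
  order — note that balancing before testing inflates significance, which
  is why the flag exists).  `smote_k` ≥ minority size is clamped with a
  warning; a minority of one is a hard error.
- **Max–min normalisation.** Per row, (x − min)/(max − min). Constant rows
  map to zeros with a warning. Normalisation is per-miRNA across samples;
  the axis matters only for visual comparability since the downstream
  statistics are computed on the pre-normalised scale (below).

## Differential expression

- **Fold change** is log₂((mean tumor + ε)/(mean normal + ε)) with
  pseudocount ε = 10⁻⁶, computed on the imputed, pre-normalisation matrix:
  max–min rescaling destroys ratio meaning. This is a deliberate design
  choice exposed in the pipeline rather than buried.
- **Test.** Default is Welch's two-sided t-test on log₂(x + ε); a paired t
  (aligned by pair ID) and the two-sided Wilcoxon rank-sum test are
  options. Degenerate tests (zero variance) report p = 1 rather than NaN.
- **Calls.** Up iff log₂FC ≥ +1 and p < 0.05; Down iff log₂FC ≤ −1 and
  p < 0.05 (inclusive on the fold-change bound, strict on p). No
  multiple-testing correction is applied by default, matching the raw
  p < 0.05 screening convention this kind of pipeline uses.
- **SNR.** The default `sum_abs` mode scores |u₊ − u₋|/(σ₊ + σ₋) with
  sample SDs (u₊/σ₊ from normal, u₋/σ₋ from tumor samples). A `literal`
  mode computes the signed variant (u₊ − u₋)/(σ₊ − σ₋); its denominator is
  a *difference* of SDs, which is sign-unstable and undefined when the SDs
  coincide (flagged as NaN with a warning, never silently dropped). The
  conventional sum-of-SDs form is the default because a separation score
  should be positive for both up- and down-regulated markers. The screen
  keeps SNR ≥ `snr_min` (default 1.0).
- **Intersection.** The SDE set is the intersection of the per-dataset
  significant sets over all (≥ 2 generalises naturally) discovery
  datasets.

## NOG and independent regulation

On the bipartite miRNA→gene network (edges merged by union across source
databases, with per-edge provenance retained), a gene with in-degree 1 is
independently regulated; NOG(m) counts the genes whose sole regulator is m.
The invariant Σₘ NOG(m) = #{genes with in-degree 1} is enforced by test.
The NOG distribution summary fits a power-law exponent by least squares on
log frequency vs log value over NOG values ≥ 1, mirroring how such
distributions are usually presented graphically; the fit is reported as
undefined with fewer than three distinct positive values. This
frequency-regression estimator is known to be biased when tail counts are
singletons — recovery checks therefore use samples large enough to
populate the tail (20 000 draws), where it is unbiased in practice.

## AUC evaluation

AUC is computed from the rank statistic U/(n₁n₂) with ties counted ½ — the
probability that a random tumor sample outranks a random normal one — and
is verified against the trapezoidal area under the empirical ROC curve to
10⁻¹² (both are implemented; the identity is exercised in the tests).
Direction folding (default on) reports max(A, 1 − A) plus the implied
direction, making the score sign-agnostic, as required when down-regulated
markers are screened on the same AUC ≥ 0.9 bar as up-regulated ones.
Constant score vectors yield 0.5 with a warning. Candidates are filtered
(AUC ≥ `auc_min` AND NOG ≥ `nog_min`) *first* and then truncated to the
`top_k` largest AUCs (ties: higher NOG, then lexicographic ID) — the
filter-then-truncate order matters when more than `top_k` miRNAs pass.

## Centrality measures and hub consensus

Definitions are frozen in `mirmarker.centrality` (module docstring) so any
divergence from other implementations is auditable. Choices worth noting:

- **Closeness is harmonic** (Σ 1/d, unreachable = 0) so it stays finite on
  disconnected graphs — real PPI exports are almost never connected.
- **Radiality** is computed per connected component with that component's
  diameter; singleton components score 0.
- **DMNC** uses exponent ε = 1.7 (configurable); ties in the maximum
  neighbourhood component's order break toward more edges.
- **MCC** sums (|C| − 1)! over maximal cliques C ∋ v with |C| ≥ 2 (an
  isolated node scores 0); maximal cliques come from networkx's
  Bron–Kerbosch enumeration.
- **Betweenness and Stress** share one Brandes-style BFS accumulation,
  summed over unordered pairs; both are cross-checked against networkx and
  against exhaustive path enumeration on every connected graph with ≤ 7
  nodes.
- **EPC** is Monte-Carlo: each iteration draws a keep probability
  p ~ U[0, 1] once, retains each edge independently with probability p,
  and adds (#nodes still connected to v)/n. Deterministic given the seed;
  default 100 iterations. Because all edges share one p per iteration,
  iterations are strongly correlated across nodes: per-node means converge
  at the usual √iters rate (verified against exact subset-enumeration
  expectations on paths and cliques), but *fine rankings* stabilise slowly
  — at 100 iterations EPC separates hubs from the bulk (all that the
  quartile cut needs) without resolving neighbouring ranks. Raise
  `epc_iters` when the ranking itself matters.

Hub genes must exceed the per-method upper quartile (linear-interpolation
quantile over all nodes of the table, strict >) in **all nine** measures.
With heavy ties (e.g. all scores equal) the hub set is legitimately empty.
Fewer than four nodes is a hard error. The pipeline computes centralities
on the PPI graph exactly as given: the input contract is an export already
restricted to the target-gene universe of interest, which is how such
exports are produced upstream.

## Synthetic data

The generators emulate the structure the analysis assumes, not real assay
physics:

- **Expression**: log-normal measurements (per-miRNA baselines uniform on
  [4, 10] log₂ units), a shared per-pair random effect (SD 0.3 log₂ units)
  mimicking paired tumor/paraneoplastic tissue, i.i.d. Gaussian log₂ noise
  (default SD 0.5), planted DE rows shifted ±`effect_log2` (default 3) in
  tumor samples, and i.i.d. missingness. Defaults — 40 pairs, 300 miRNAs,
  10 DE — are sized like a mid-sized discovery cohort.
- **Regulatory network**: miRNA out-degrees drawn from a discrete power
  law (default exponent −2, capped at 50); planted uniquely-targeted genes
  wired with in-degree exactly 1 by construction; all other genes topped
  up to ≥ 2 regulators so planted NOG values are exact (deterministic
  post-hoc wiring rather than rejection sampling, for speed and
  reproducibility).
- **PPI**: preferential-attachment backbone (m = 2) with the node→gene
  assignment shuffled, so planted hubs start as ordinary nodes; each hub
  is then embedded in a clique (default size 8) plus extra random
  attachments (default 12), which lifts it above the upper quartile on
  degree-, clique- and path-based measures alike. Edge confidences are
  drawn strictly above 0.9.
- **Pathways**: sparse random assignment; the planted gene is guaranteed a
  relevant pathway, and background genes draw only from non-relevant
  pathways by default (disease-pathway membership is sparse; a
  `background_relevant` flag allows leakage).

The coherent bundle plants one biomarker triple (marker miRNA with NOG = 4,
one of its unique targets embedded as a hub and annotated to the relevant
pathway) and two decoy miRNAs with NOG = 3 whose unique targets are
ordinary PPI nodes. What passing recovery tests shows: the pipeline's
stages compose correctly and its thresholds behave as specified under the
assumed structure. What it does not show: robustness to count overdispersion,
batch effects, annotation errors, or the identifier-mapping noise of real
multi-database merges — none of which the generators model.

## Numerical and interface conventions

- Missing tokens in TSV input: empty string, `NA`, `NaN` (any case),
  `N/A`; any other non-numeric cell also becomes missing.
- Cells are parsed with exact strtod float conversion so written files
  round-trip bit-identically (pandas' numeric coercion is not exact).
- miRNA IDs are trimmed and lower-cased, gene symbols trimmed and
  upper-cased (miRBase names are case-insensitive in the wild); both
  configurable.
- STRING-style combined scores auto-detect the 0–1000 integer scale (any
  value > 1) and normalise to [0, 1]; the score filter is strict
  (> `ppi_min_score`), matching "greater than 0.9" semantics. Self-loops
  are dropped with a warning; duplicate edges keep the maximum score.
- Identical config + seed reproduces every output file byte-identically.

## Problem sizes used in the checks

The recovery study runs 20 planted-signal and 20 null bundles (40 paired
samples × 300 miRNAs each, 600-gene regulatory network, 250-node PPI); the
AUC identity uses 500–1000 random score vectors; NOG conservation uses 500
random bipartite graphs; the centrality oracle covers every connected
graph on ≤ 7 nodes (996 isomorphism classes from the networkx graph
atlas). These sizes were chosen as the smallest at which each property is
statistically meaningful.

## Known limitations

- No identifier-mapping service: merging real regulation databases
  requires the user to harmonise gene/miRNA namespaces first.
- No count-model differential expression (negative binomial etc.), no
  covariate adjustment, no batch correction, no library-size or quantile
  normalisation.
- The hub consensus quartile is computed over all nodes of the score
  table; on very large PPI graphs dominated by low-degree nodes this makes
  the bar easier to clear than a quartile over a pre-ranked subset would.
- AUC confidence intervals and survival analysis are out of scope.
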