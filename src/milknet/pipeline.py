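"""End-to-end orchestration: ingest -> filter -> outliers -> impute ->
combine -> GGM -> local-fdr edges -> Leiden/CPM -> retained clusters ->
enrichment -> peptidome analyses.

Also hosts the synthetic study generator that drives testing: a planted
block GGM over ~297 samples for proteins, an in-silico K/R digest of a
subset of those proteins for peptides, and left-censored missingness —
the complete study conditions with ground truth attached.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
from sklearn.metrics import adjusted_rand_score

from . import calibration, community, enrichment, ggm, ingest, peptidome, synthetic
from .containers import AbundanceTable, combine

__version__ = "0.1.0"


@dataclass(frozen=True)
class PipelineConfig:
    """All thresholds of the analysis, serializable and echoed per run."""

    min_present_fraction: float = 0.5
    outlier_log10_margin: float = 2.0
    impute_iterations: int = 10
    lfdr_threshold: float = 0.1
    leiden_resolution: float = 1e-3
    leiden_beta: float = 0.01
    leiden_iterations: int = 1000
    leiden_use_weights: bool = True
    min_cluster_size: int = 4
    enrichment_alpha: float = 0.05
    ladder_min_peptides: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.lfdr_threshold <= 1:
            raise ValueError("lfdr_threshold must lie in (0, 1]")
        if not 0 <= self.min_present_fraction < 1:
            raise ValueError("min_present_fraction must lie in [0, 1)")
        if self.min_cluster_size < 1:
            raise ValueError("min_cluster_size must be >= 1")


@dataclass(frozen=True)
class SyntheticScenario:
    """Study conditions of the synthetic cohort.

    Defaults emulate the analysed milk cohort at desk scale: 297 samples;
    proteins organised in partial-correlation blocks of 4 at rho = 0.3
    (the largest constant-pcor block magnitude that keeps blocks of 4
    comfortably positive definite) plus unstructured background proteins;
    two secreted precursors digested at K/R bonds with two-step
    exoproteolytic trimming; 20% left-censored missingness per feature.
    """

    n_samples: int = 297
    n_features: int = 40
    block_sizes: tuple[int, ...] = (4, 4, 4, 4)
    within_block_pcor: float = 0.3
    n_precursors: int = 2
    precursor_length: int = 150
    cleavage_prob: float = 0.7
    exo_steps: int = 2
    coupling_sigma: float = 1.0
    censor_quantile: float = 0.2


@dataclass
class SyntheticStudy:
    protein_table: AbundanceTable
    peptide_table: AbundanceTable
    precursor_sequences: dict[str, str]
    truth: synthetic.SyntheticTruth


def simulate_study(scenario: SyntheticScenario, seed: int) -> SyntheticStudy:
    """Generate the full two-table study with ground truth.

    Precursor proteins are background (non-block) features — the heavily
    degraded milk precursors are secreted proteins, not members of the
    transport-driven protein clusters. Each peptide's planted cluster is
    its proteolysis tree (base fragment plus trim variants): in the
    generative conditional-independence graph a ladder is its own
    community, attached to its precursor by a single coupling edge.
    """
    prec_spec = synthetic.PrecisionSpec(
        n_features=scenario.n_features,
        block_sizes=scenario.block_sizes,
        within_block_pcor=scenario.within_block_pcor,
        n_samples=scenario.n_samples,
        seed=seed,
    )
    protein_table, truth = synthetic.simulate_abundances(prec_spec)

    n_block_features = int(sum(scenario.block_sizes))
    if scenario.n_features - n_block_features < scenario.n_precursors:
        raise ValueError("not enough background features to serve as precursors")
    precursor_ids = protein_table.feature_ids[
        n_block_features : n_block_features + scenario.n_precursors
    ]
    sequences = {
        acc: synthetic.random_protein_sequence(scenario.precursor_length, seed=seed + 10 + i)
        for i, acc in enumerate(precursor_ids)
    }
    digest_spec = synthetic.DigestSpec(
        precursor_sequences=sequences,
        cleavage_prob=scenario.cleavage_prob,
        exo_steps=scenario.exo_steps,
        coupling_sigma=scenario.coupling_sigma,
        seed=seed + 1,
    )
    peptide_table, digest_truth = synthetic.simulate_digest(
        digest_spec, protein_table.intensities[precursor_ids]
    )
    # digest truth carries the cascade edges and per-tree peptide clusters;
    # offset tree ids past the protein block ids to keep labels unique
    n_blocks = len(scenario.block_sizes)
    for pid, tree in digest_truth.true_clusters.items():
        digest_truth.true_clusters[pid] = n_blocks + tree
    truth = truth.merge(digest_truth)

    if scenario.censor_quantile > 0:
        truth.censor_thresholds = {
            **synthetic.censor_thresholds(protein_table, scenario.censor_quantile),
            **synthetic.censor_thresholds(peptide_table, scenario.censor_quantile),
        }
        protein_table = synthetic.apply_mnar_censoring(
            protein_table, scenario.censor_quantile, seed=seed + 2
        )
        peptide_table = synthetic.apply_mnar_censoring(
            peptide_table, scenario.censor_quantile, seed=seed + 3
        )
    return SyntheticStudy(protein_table, peptide_table, sequences, truth)


@dataclass
class RunReport:
    """Per-stage counts plus summaries; deterministic under a fixed seed."""

    counts: dict = field(default_factory=dict)
    network: dict = field(default_factory=dict)
    clusters: dict = field(default_factory=dict)
    peptidome: dict = field(default_factory=dict)
    config: dict = field(default_factory=dict)
    seed: int = 0
    version: str = __version__

    def to_json(self) -> str:
        payload = asdict(self)
        return json.dumps(payload, sort_keys=True, default=_jsonable)

    def report_hash(self) -> str:
        return hashlib.sha256(self.to_json().encode()).hexdigest()

    def write(self, path: str | Path) -> None:
        Path(path).write_text(self.to_json())


def _jsonable(x):
    if isinstance(x, (np.integer,)):
        return int(x)
    if isinstance(x, (np.floating,)):
        return float(x)
    if isinstance(x, (set, frozenset, tuple)):
        return sorted(x) if isinstance(x, (set, frozenset)) else list(x)
    raise TypeError(f"not JSON-serializable: {type(x)}")


@dataclass
class PipelineResult:
    report: RunReport
    combined: AbundanceTable
    pcm: ggm.PartialCorrelationMatrix
    shrinkage: ggm.ShrinkageFit
    edges: pd.DataFrame
    graph: nx.Graph
    partition: community.Partition
    retained: list[community.ClusterRecord]
    enrichments: pd.DataFrame
    ladders: list[peptidome.LadderRecord]
    specificity: dict[str, float]
    contributions: pd.DataFrame


def run_pipeline(
    protein_table: AbundanceTable,
    peptide_table: AbundanceTable,
    config: PipelineConfig | None = None,
    precursor_sequences: dict[str, str] | None = None,
    annotations: enrichment.AnnotationSet | None = None,
) -> PipelineResult:
    """Execute the complete analysis on a protein + peptide table pair."""
    config = config or PipelineConfig()
    counts: dict[str, int] = {
        "proteins_in": protein_table.n_features,
        "peptides_in": peptide_table.n_features,
        "samples_in": protein_table.n_samples,
    }

    # 1-2: contaminant/prevalence filter, then peptide-total outliers
    protein_table = ingest.filter_features(protein_table, config.min_present_fraction)
    peptide_table = ingest.filter_features(peptide_table, config.min_present_fraction)
    outliers = ingest.flag_outlier_samples(peptide_table, config.outlier_log10_margin)
    if outliers:
        protein_table = protein_table.drop_samples(outliers)
        peptide_table = peptide_table.drop_samples(outliers)
    counts.update(
        proteins_filtered=protein_table.n_features,
        peptides_filtered=peptide_table.n_features,
        samples_dropped=len(outliers),
        samples_used=protein_table.n_samples,
    )

    # 3: left-censored imputation (per table, deterministic seeds)
    protein_table = ingest.impute_mnar(
        protein_table, seed=config.seed + 101, n_iterations=config.impute_iterations
    )
    peptide_table = ingest.impute_mnar(
        peptide_table, seed=config.seed + 102, n_iterations=config.impute_iterations
    )

    # 4-6: combined matrix -> shrinkage GGM -> calibrated edge list
    combined = combine([protein_table, peptide_table])
    pcm, fit = ggm.partial_correlations(combined.log2_matrix())
    edges = calibration.significant_edges(pcm, threshold=config.lfdr_threshold)
    network = calibration.network_summary(edges, combined.kind)
    network["lambda_star"] = fit.lambda_star

    # 7-9: Leiden/CPM communities on the significant-edge network
    graph = nx.Graph()
    graph.add_nodes_from(
        sorted(set(edges.loc[edges["significant"], "feature_i"])
               | set(edges.loc[edges["significant"], "feature_j"]))
    )
    for row in edges[edges["significant"]].itertuples():
        graph.add_edge(row.feature_i, row.feature_j, weight=abs(float(row.rho)), rho=float(row.rho))
    params = community.LeidenParams(
        resolution=config.leiden_resolution,
        beta=config.leiden_beta,
        iterations=config.leiden_iterations,
        seed=config.seed,
        use_weights=config.leiden_use_weights,
    )
    partition = community.leiden_cpm(graph, params)
    retained = community.retain_clusters(partition, combined.kind, config.min_cluster_size)
    cluster_counts = community.composition_counts(retained)

    # 10: GO overrepresentation of protein members, all proteins background
    background = [
        str(protein_table.meta.at[f, "gene_name"]) if "gene_name" in protein_table.meta.columns else f
        for f in protein_table.feature_ids
    ]
    gene_of = dict(zip(protein_table.feature_ids, background))
    enrichments = pd.DataFrame()
    if annotations is not None:
        frames = []
        for rec in retained:
            genes = [gene_of[m] for m in rec.members if m in gene_of]
            if not genes:
                continue
            frames.append(
                enrichment.enrich_cluster(rec.cluster_id, genes, background, annotations)
            )
        if frames:
            enrichments = enrichment.significant_enrichments(
                pd.concat(frames, ignore_index=True), config.enrichment_alpha
            )

    # 11: peptidome analyses on retained clusters
    ladders: list[peptidome.LadderRecord] = []
    locations_by_cluster: dict[int, list[peptidome.PeptideLocation]] = {}
    meta = peptide_table.meta
    for rec in retained:
        locs = [
            peptidome.PeptideLocation(
                str(meta.at[m, "precursor_accession"]),
                int(meta.at[m, "start"]),
                int(meta.at[m, "end"]),
                str(meta.at[m, "sequence"]),
            )
            for m in rec.members
            if m in meta.index
        ]
        if locs:
            locations_by_cluster[rec.cluster_id] = locs
            ladders.extend(
                peptidome.detect_ladders(locs, config.ladder_min_peptides, rec.cluster_id)
            )
    specificity: dict[str, float] = {}
    if precursor_sequences:
        all_locs = [l for locs in locations_by_cluster.values() for l in locs]
        if all_locs:
            _, specificity = peptidome.cleavage_specificity(all_locs, precursor_sequences)
    contributions = (
        peptidome.precursor_contribution(peptide_table)
        if "precursor_accession" in meta.columns
        else pd.DataFrame()
    )

    pep_summary = {
        "n_ladders": len(ladders),
        "n_trimming_steps": sum(
            len(peptidome.trimming_steps(l.members)) for l in ladders
        ),
        "specificity_percent": specificity,
    }
    report = RunReport(
        counts=counts,
        network=network,
        clusters=cluster_counts,
        peptidome=pep_summary,
        config=asdict(config),
        seed=config.seed,
    )
    if cluster_counts["total"] != (
        cluster_counts["both"] + cluster_counts["protein"] + cluster_counts["peptide"]
    ):
        raise AssertionError("cluster composition counts do not sum to total")
    return PipelineResult(
        report=report,
        combined=combined,
        pcm=pcm,
        shrinkage=fit,
        edges=edges,
        graph=graph,
        partition=partition,
        retained=retained,
        enrichments=enrichments,
        ladders=ladders,
        specificity=specificity,
        contributions=contributions,
    )


# ---------------------------------------------------------------------------
# Recovery metrics against planted truth
# ---------------------------------------------------------------------------

def edge_recovery(
    edges: pd.DataFrame, truth: synthetic.SyntheticTruth, feature_ids: list[str]
) -> dict[str, float]:
    """Empirical FDR and sensitivity of the significant-edge set against
    the planted edges (restricted to features present in the matrix)."""
    present = set(feature_ids)
    planted = {
        frozenset(e) for e in truth.true_edges if e[0] in present and e[1] in present
    }
    sig = edges[edges["significant"]]
    predicted = {frozenset((a, b)) for a, b in zip(sig["feature_i"], sig["feature_j"])}
    tp = len(predicted & planted)
    fp = len(predicted - planted)
    return {
        "fdr": fp / max(len(predicted), 1),
        "sensitivity": tp / max(len(planted), 1),
        "n_predicted": len(predicted),
        "n_planted": len(planted),
    }


def cluster_recovery_ari(
    retained: list[community.ClusterRecord], truth: synthetic.SyntheticTruth
) -> float:
    """Adjusted Rand index between recovered (retained) clusters and the
    planted clustering, over nodes assigned to retained clusters."""
    nodes, found, planted = [], [], []
    for rec in retained:
        for m in rec.members:
            if m in truth.true_clusters:
                nodes.append(m)
                found.append(rec.cluster_id)
                planted.append(truth.true_clusters[m])
    if not nodes:
        return 0.0
    return float(adjusted_rand_score(planted, found))


def summarize_counts(report: RunReport) -> str:
    """Human-readable one-screen summary of a run."""
    n = report.network
    c = report.clusters
    lines = [
        f"samples used: {report.counts.get('samples_used', '?')}"
        f" (dropped {report.counts.get('samples_dropped', 0)} outliers)",
        f"features: {report.counts.get('proteins_filtered', 0)} proteins"
        f" + {report.counts.get('peptides_filtered', 0)} peptides",
        f"network: {n.get('n_edges', 0)} edges connecting {n.get('n_nodes', 0)} nodes"
        f" ({n.get('n_protein_nodes', 0)} proteins + {n.get('n_peptide_nodes', 0)} peptides)",
        f"density: {n.get('density_percent', 0.0):.1f}% of all possible edges",
        f"same-kind edges: {n.get('same_kind_percent', 0.0):.1f}%",
        f"clusters retained: {c.get('total', 0)} = {c.get('both', 0)} mixed"
        f" + {c.get('protein', 0)} protein-only + {c.get('peptide', 0)} peptide-only",
        f"peptide ladders: {report.peptidome.get('n_ladders', 0)}",
    ]
    return "\n".join(lines)
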