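"""End-to-end orchestration of the multiome pipeline on synthetic data.

Runs every stage in order — QC, normalization, markers, peak merging, peak
counting, gene activity scores, motif deviations, positive regulators,
peak-to-gene links, the disease-filtered GRN, driver genes, phases, primed
genes, regulons, cross-species conservation, and regulon modules — and scores
each stage against the generator's planted ground truth.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import adjusted_rand_score

from . import atac, linkage, markers, motifs, regulons, trajectory
from .config import AnalysisConfig
from .core import CountMatrix, FeatureMatrix, MultiomeDataset, is_disease
from .simulate import SimulatedMultiome, SimulationDesign, simulate_multiome

logger = logging.getLogger("sfmultiome.pipeline")


@dataclass
class PipelineResult:
    sim: SimulatedMultiome
    normalized: FeatureMatrix
    cluster_markers: dict[str, pd.DataFrame]
    upregulated: dict[str, list[str]]
    merged_peaks: pd.DataFrame
    peak_counts: CountMatrix
    gene_scores: FeatureMatrix
    deviations: motifs.DeviationMatrix
    regulators: pd.DataFrame
    disease_up_genes: list[str]
    disease_open_peaks: list[str]
    links_all: pd.DataFrame
    link_classes: pd.DataFrame
    grn: pd.DataFrame
    disease_grn: pd.DataFrame
    drivers: pd.DataFrame
    phases: pd.DataFrame
    primed: pd.DataFrame
    regulons_a: list[regulons.Regulon]
    regulons_b: list[regulons.Regulon]
    conserved: pd.DataFrame
    modules: pd.DataFrame
    metrics: dict[str, float] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# stage helpers

def marker_recovery(
    upregulated: dict[str, list[str]], truth
) -> tuple[float, float]:
    """Sensitivity over planted cluster markers and observed FDR.

    A reported (cluster, gene) call counts as false only if the gene has no
    planted elevation in that cluster (regulon targets and trajectory genes
    genuinely elevated there are not false positives).
    """
    tp = total = 0
    fp = reported = 0
    for cluster, planted in truth.marker_genes.items():
        called = set(upregulated.get(cluster, []))
        tp += len(called & set(planted))
        total += len(planted)
        reported += len(called)
        fp += len(called - truth.elevated.get(cluster, set()))
    sens = tp / total if total else 0.0
    fdr = fp / reported if reported else 0.0
    return sens, fdr


def differential_open_peaks(
    peak_counts: CountMatrix, disease_mask: np.ndarray, cfg: AnalysisConfig
) -> list[str]:
    """Peaks with increased accessibility in disease (log2FC and p cutoffs)."""
    norm = markers.normalize_expression(peak_counts, cfg)
    res = markers.find_markers(
        norm, np.where(disease_mask, "disease", "healthy"), "disease", cfg,
        lfc_base="2", marker_filters=False,
    )
    sel = res[(res["avg_lfc"] > cfg.peak_lfc) & (res["p"] < cfg.peak_p)]
    return sel["feature_id"].tolist()


def _prf(called: set, truth_set: set) -> tuple[float, float]:
    precision = len(called & truth_set) / len(called) if called else 0.0
    recall = len(called & truth_set) / len(truth_set) if truth_set else 0.0
    return precision, recall


def run_pipeline(
    design: SimulationDesign | None = None,
    cfg: AnalysisConfig | None = None,
    sim: SimulatedMultiome | None = None,
    with_species_b: bool = True,
) -> PipelineResult:
    design = design or SimulationDesign()
    cfg = cfg or AnalysisConfig()
    if sim is None:
        sim = simulate_multiome(design)
    data = sim.data
    truth = sim.truth
    meta = data.metadata
    labels = meta["cluster_label"].to_numpy()
    disease_mask = is_disease(meta["condition"])
    metrics: dict[str, float] = {}

    # --- scRNA: QC, normalization, markers -------------------------------
    retained = markers.filter_cells(data.expression, meta, cfg)
    expr = data.expression.subset_cells(retained)
    meta = meta[meta["cell_id"].isin(set(retained))].reset_index(drop=True)
    labels = meta["cluster_label"].to_numpy()
    disease_mask = is_disease(meta["condition"])
    norm = markers.normalize_expression(expr, cfg)

    cluster_markers = {}
    upregulated = {}
    for c in design.cluster_names:
        res = markers.find_markers(norm, labels, c, cfg)
        cluster_markers[c] = res
        upregulated[c] = markers.select_upregulated(res, cfg)
    sens, fdr = marker_recovery(upregulated, truth)
    metrics["marker_sensitivity"] = sens
    metrics["marker_fdr"] = fdr
    logger.info("[pipeline] marker recovery: sensitivity %.3f, FDR %.3f", sens, fdr)

    # --- scATAC: merged peaks, peak counts, gene scores ------------------
    merged_peaks = atac.iterative_overlap_merge(data.candidate_peaks)
    metrics["n_merged_peaks"] = float(len(merged_peaks))
    peak_counts = atac.count_fragments_in_peaks(
        data.fragments, merged_peaks, cell_ids=meta["cell_id"].tolist()
    )
    gene_scores = atac.gene_activity_scores(data.tiles.subset_cells(retained),
                                            data.genes, cfg)
    metrics["gene_score_rank_corr"] = gene_score_rank_correlation(
        gene_scores, meta, truth
    )

    # --- motifs: deviations and positive regulators ----------------------
    annotation = motifs.annotate_motifs(merged_peaks, data.motif_hits)
    backgrounds = motifs.sample_background_peaks(
        peak_counts, cfg.n_background, cfg.n_bins, cfg.seed
    )
    deviations = motifs.motif_deviations(peak_counts, annotation, backgrounds)
    grouping = (
        meta["cluster_label"].astype(str) + "|" + meta["condition"].astype(str)
    ).to_numpy()
    candidates = truth.tf_ids + truth.decoy_motifs
    regulators = motifs.positive_regulators(deviations, norm, candidates,
                                            grouping, cfg)
    pos = set(regulators[regulators["positive"]]["tf_id"])
    metrics["planted_tf_recovered"] = float(len(pos & set(truth.tf_ids)))
    metrics["n_planted_tfs"] = float(len(truth.tf_ids))
    metrics["decoy_rejection_rate"] = (
        1.0 - len(pos & set(truth.decoy_motifs)) / len(truth.decoy_motifs)
        if truth.decoy_motifs else 1.0
    )

    # --- disease contrasts ------------------------------------------------
    disease_labels = np.where(disease_mask, "disease", "healthy")
    disease_de = markers.find_markers(norm, disease_labels, "disease", cfg)
    disease_up_genes = markers.select_upregulated(disease_de, cfg)
    disease_open = differential_open_peaks(peak_counts, disease_mask, cfg)

    # --- peak-to-gene links and the GRN -----------------------------------
    links_all = linkage.peak2gene_links(
        peak_counts, norm, merged_peaks, data.genes, meta, cfg
    )
    metrics["n_peak2gene_links"] = float(len(links_all))
    links_h = linkage.peak2gene_links(
        peak_counts, norm, merged_peaks, data.genes, meta, cfg,
        cells=meta["cell_id"][~disease_mask].tolist(),
    )
    links_d = linkage.peak2gene_links(
        peak_counts, norm, merged_peaks, data.genes, meta, cfg,
        cells=meta["cell_id"][disease_mask].tolist(),
    )
    link_classes = linkage.classify_links(links_h, links_d)
    for cls in ("shared", "disease_only", "healthy_only"):
        metrics[f"links_{cls}"] = float(
            (link_classes["condition_class"] == cls).sum()
        )

    regulator_tfs = sorted(pos & set(truth.tf_ids)) or truth.tf_ids
    grn = linkage.tf_gene_links(links_all, annotation, regulator_tfs)
    disease_grn = linkage.filter_disease_grn(grn, disease_up_genes, disease_open)
    called_edges = set(map(tuple, disease_grn[["tf_id", "gene_id"]].to_numpy()))
    precision, recall = _prf(called_edges, truth.disease_edges)
    metrics["grn_edge_precision"] = precision
    metrics["grn_edge_recall"] = recall

    # --- trajectory: drivers, phases, priming ------------------------------
    intercluster = sorted(set().union(*upregulated.values())) if upregulated else []
    metrics["n_intercluster_de"] = float(len(intercluster))
    pathogenic_de = {}
    for c in design.expanding_clusters:
        sub_cells = meta["cell_id"][labels == c].tolist()
        sub_norm = norm.subset_cells(sub_cells)
        sub_lab = np.where(
            is_disease(meta.set_index("cell_id").loc[sub_cells, "condition"]),
            "disease", "healthy",
        )
        res = markers.find_markers(sub_norm, sub_lab, "disease", cfg)
        pathogenic_de[c] = markers.select_upregulated(res, cfg)
    drivers = trajectory.select_driver_genes(
        intercluster, pathogenic_de, truth.likelihood, cfg
    )
    selected = drivers[drivers["selected"]]["gene_id"].tolist()
    metrics["n_driver_genes"] = float(len(selected))
    truth_drivers = set(truth.driver_genes)
    union = set(selected) | truth_drivers
    metrics["driver_jaccard"] = (
        len(set(selected) & truth_drivers) / len(union) if union else 0.0
    )

    phases = pd.DataFrame(columns=["gene_id", "phase", "t_half"])
    metrics["phase_time_spearman"] = 0.0
    if len(selected) >= 3:
        phases = trajectory.assign_phases(
            norm, selected, meta["latent_time"].to_numpy()
        )
        timed = phases[phases["gene_id"].isin(truth.activation_time)]
        if len(timed) >= 3:
            order = {"early": 0, "intermediate": 1, "late": 2}
            rho = stats.spearmanr(
                timed["phase"].map(order),
                [truth.activation_time[g] for g in timed["gene_id"]],
            ).statistic
            metrics["phase_time_spearman"] = float(rho)

    downstream = [c for c in design.cluster_names if c != design.root_cluster]
    primed = trajectory.call_primed_genes(
        norm, meta, design.root_cluster, downstream, upregulated,
        disease_up_genes, peak_counts, merged_peaks, data.genes, cfg,
    )
    called_primed = set(primed[primed["primed"]]["gene_id"])
    p_precision, p_recall = _prf(called_primed, set(truth.primed_genes))
    metrics["primed_sensitivity"] = p_recall
    metrics["primed_fdr"] = 1.0 - p_precision if called_primed else 0.0
    metrics["n_primed_genes"] = float(len(called_primed))

    # --- regulons and cross-species ---------------------------------------
    regulons_a = regulons.infer_regulons(
        norm, truth.tf_ids, truth.motif_prior, cfg.top_k, cfg.min_targets
    )
    precisions, recalls = [], []
    for r in regulons_a:
        p, rc = _prf(set(r.targets), set(truth.regulon_targets[r.tf_id]))
        precisions.append(p)
        recalls.append(rc)
    metrics["regulon_precision"] = float(np.mean(precisions)) if precisions else 0.0
    metrics["regulon_recall"] = float(np.mean(recalls)) if recalls else 0.0

    regulons_b = []
    conserved = pd.DataFrame(columns=["tf_id", "conserved_targets", "n_targets_a",
                                      "n_targets_b", "jaccard"])
    if with_species_b:
        regulons_b, conserved = cross_species_stage(sim, cfg)
        metrics["n_conserved_regulons"] = float(len(conserved))

    modules = regulons.cluster_regulon_modules(
        deviations, truth.tf_ids, k=len(set(truth.tf_program.values()))
    )
    planted_programs = [truth.tf_program[tf] for tf in modules["tf_id"]]
    metrics["module_ari"] = float(
        adjusted_rand_score(planted_programs, modules["module"])
    )

    return PipelineResult(
        sim=sim, normalized=norm, cluster_markers=cluster_markers,
        upregulated=upregulated, merged_peaks=merged_peaks,
        peak_counts=peak_counts, gene_scores=gene_scores,
        deviations=deviations, regulators=regulators,
        disease_up_genes=disease_up_genes, disease_open_peaks=disease_open,
        links_all=links_all, link_classes=link_classes, grn=grn,
        disease_grn=disease_grn, drivers=drivers, phases=phases, primed=primed,
        regulons_a=regulons_a, regulons_b=regulons_b, conserved=conserved,
        modules=modules, metrics=metrics,
    )


def cross_species_stage(
    sim: SimulatedMultiome, cfg: AnalysisConfig
) -> tuple[list[regulons.Regulon], pd.DataFrame]:
    """Second-species replicate: an independent simulation in its own gene
    namespace, regulon inference there, and homolog-mapped conservation."""
    design_b = replace(sim.design, seed=sim.design.seed + 1000)
    sim_b = simulate_multiome(design_b)
    expr_b = sim_b.data.expression
    prefixed = np.asarray([f"ms_{g}" for g in expr_b.feature_ids], dtype=object)
    expr_b = CountMatrix(prefixed, expr_b.cell_ids, expr_b.values)
    norm_b = markers.normalize_expression(expr_b, cfg)
    prior_b = {
        f"ms_{tf}": {f"ms_{g}" for g in genes}
        for tf, genes in sim_b.truth.motif_prior.items()
    }
    regulons_b = regulons.infer_regulons(
        norm_b, [f"ms_{tf}" for tf in sim_b.truth.tf_ids], prior_b,
        cfg.top_k, cfg.min_targets,
    )
    homologs = pd.DataFrame(
        {
            "gene_a": sim.data.expression.feature_ids,
            "gene_b": [f"ms_{g}" for g in sim.data.expression.feature_ids],
        }
    )
    norm_a = markers.normalize_expression(sim.data.expression, cfg)
    regulons_a = regulons.infer_regulons(
        norm_a, sim.truth.tf_ids, sim.truth.motif_prior, cfg.top_k, cfg.min_targets
    )
    conserved = regulons.conserved_regulons(regulons_a, regulons_b, homologs)
    return regulons_b, conserved


def gene_score_rank_correlation(
    gene_scores: FeatureMatrix, meta: pd.DataFrame, truth
) -> float:
    """Spearman correlation between planted promoter openness and observed
    mean gene activity, per-gene centered across clusters.

    Centering removes each gene's window baseline (neighboring peaks
    contribute a gene-independent offset), so the statistic measures whether
    the cluster profile of the activity score tracks the planted promoter
    accessibility profile.
    """
    marker_genes = sorted(set().union(*(set(v) for v in truth.marker_genes.values())))
    clusters = list(truth.promoter_log_openness.columns)
    truth_m = truth.promoter_log_openness.loc[marker_genes, clusters].to_numpy()
    X = gene_scores.subset_features(marker_genes).dense()
    labels = meta.set_index("cell_id").loc[list(gene_scores.cell_ids),
                                           "cluster_label"].to_numpy()
    obs = np.column_stack([X[:, labels == c].mean(axis=1) for c in clusters])
    truth_c = truth_m - truth_m.mean(axis=1, keepdims=True)
    obs_c = obs - obs.mean(axis=1, keepdims=True)
    rho = stats.spearmanr(truth_c.ravel(), obs_c.ravel()).statistic
    return float(rho)
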