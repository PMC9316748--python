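"""Driver-gene selection, activation-phase assignment, and primed-gene calling.

The trajectory consumes a per-cell latent time with a designated root cluster
(both inputs, mirroring upstream velocity analysis). Driver genes intersect
cluster-and-disease-specific DE genes with high driver-likelihood scores;
phases come from hierarchical clustering of latent-time-smoothed expression;
"primed" genes are transcriptionally silent in the root state, activated in
downstream states, upregulated in disease, yet already carry an open promoter
in the root.
"""

from __future__ import annotations

import logging
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage

from .config import AnalysisConfig
from .core import CountMatrix, FeatureMatrix, is_disease

logger = logging.getLogger("sfmultiome.trajectory")

PHASES = ["early", "intermediate", "late"]


def select_driver_genes(
    intercluster_de_genes: Sequence[str],
    pathogenic_disease_de: Mapping[str, Sequence[str]],
    likelihood: Mapping[str, float] | pd.Series,
    cfg: AnalysisConfig | None = None,
) -> pd.DataFrame:
    """Two-step driver-gene selection.

    Step 1: restrict inter-cluster DE genes to those also DE in at least one
    designated pathogenic cluster's disease contrast. Step 2: keep genes whose
    driver-likelihood score reaches the configured quantile of all supplied
    scores (default top 15%). Genes missing a likelihood are treated as 0 and
    logged.
    """
    cfg = cfg or AnalysisConfig()
    likelihood = pd.Series(likelihood, dtype=float)
    disease_specific = set()
    for genes in pathogenic_disease_de.values():
        disease_specific |= set(genes)
    step1 = [g for g in dict.fromkeys(intercluster_de_genes) if g in disease_specific]
    missing = [g for g in step1 if g not in likelihood.index]
    if missing:
        logger.warning("[drivers] %d DE genes lack a likelihood score; treated as 0",
                       len(missing))
    lk = np.array([float(likelihood.get(g, 0.0)) for g in step1])
    threshold = float(np.quantile(likelihood.to_numpy(), cfg.driver_quantile))
    selected = np.array(lk >= threshold)
    out = pd.DataFrame(
        {"gene_id": step1, "likelihood": lk, "selected": selected}
    )
    logger.info("[drivers] %d inter-cluster DE genes -> %d cluster+disease specific "
                "-> %d drivers", len(set(intercluster_de_genes)), len(step1),
                int(selected.sum()))
    return out


def empirical_likelihood(
    normalized: FeatureMatrix,
    latent_time: np.ndarray,
    labels: np.ndarray | None = None,
) -> pd.Series:
    """Data-driven driver-likelihood scores from the latent-time ordering.

    Scores each gene by its monotone association with latent time (Spearman
    rho) weighted by its normalized dynamic range across clusters (or across
    latent-time deciles when no labels are given), squashed through a sigmoid.
    This mirrors how upstream velocity tools rank putative driver genes and
    lets the ordering itself be perturbed in negative controls.
    """
    X = normalized.dense()
    latent_time = np.asarray(latent_time, dtype=float)
    if labels is None:
        labels = np.digitize(latent_time, np.quantile(latent_time, np.linspace(0, 1, 7)[1:-1]))
    labels = np.asarray(labels)
    ranks_t = stats.rankdata(latent_time)
    ranks_x = stats.rankdata(X, axis=1)
    zt = (ranks_t - ranks_t.mean()) / max(ranks_t.std(), 1e-12)
    sx = ranks_x.std(axis=1)
    zx = (ranks_x - ranks_x.mean(axis=1, keepdims=True)) / np.where(sx > 0, sx, 1.0)[:, None]
    rho = (zx @ zt) / X.shape[1]
    rho[sx == 0] = 0.0
    group_means = np.column_stack(
        [X[:, labels == g].mean(axis=1) for g in pd.unique(labels)]
    )
    rng_range = group_means.max(axis=1) - group_means.min(axis=1)
    norm_range = rng_range / np.maximum(group_means.max(axis=1), 1e-12)
    score = 1.0 / (1.0 + np.exp(-6.0 * (rho * norm_range - 0.35)))
    return pd.Series(score, index=normalized.feature_ids, name="likelihood")


def _smooth_along_time(
    X: np.ndarray, latent_time: np.ndarray, window: int
) -> tuple[np.ndarray, np.ndarray]:
    """Sliding-window mean of per-gene z-scored expression over time-ordered cells."""
    order = np.argsort(latent_time, kind="stable")
    Xo = X[:, order]
    mu = Xo.mean(axis=1, keepdims=True)
    sd = Xo.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    Z = (Xo - mu) / sd
    kernel = np.ones(window) / window
    sm = np.apply_along_axis(lambda v: np.convolve(v, kernel, mode="same"), 1, Z)
    return sm, latent_time[order]


def _half_activation_time(smoothed: np.ndarray, times: np.ndarray) -> np.ndarray:
    """Time at which each smoothed profile first reaches half its range."""
    lo = smoothed.min(axis=1, keepdims=True)
    hi = smoothed.max(axis=1, keepdims=True)
    half = (lo + hi) / 2.0
    t_half = np.empty(smoothed.shape[0])
    for i in range(smoothed.shape[0]):
        above = np.flatnonzero(smoothed[i] >= half[i])
        t_half[i] = times[above[0]] if len(above) else times[-1]
    return t_half


def assign_phases(
    normalized: FeatureMatrix,
    driver_genes: Sequence[str],
    latent_time: np.ndarray,
    k: int = 3,
    window: int | None = None,
) -> pd.DataFrame:
    """Assign early/intermediate/late activation phases to driver genes.

    Expression is z-scored per gene, smoothed by a sliding-window mean over
    latent-time-ordered cells, hierarchically clustered (average linkage,
    correlation distance) and cut into ``k`` groups, labeled by ascending mean
    half-activation time.
    """
    driver_genes = list(driver_genes)
    if len(driver_genes) < k:
        raise ValueError(f"need at least {k} genes to assign {k} phases")
    sub = normalized.subset_features(driver_genes)
    X = sub.dense()
    latent_time = np.asarray(latent_time, dtype=float)
    window = window or max(5, X.shape[1] // 20)
    sm, times = _smooth_along_time(X, latent_time, window)

    # correlation distance with a guard for zero-variance rows
    Zs = sm - sm.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(Zs, axis=1, keepdims=True)
    norms[norms == 0] = 1.0
    corr = (Zs / norms) @ (Zs / norms).T
    dist = 1.0 - corr
    iu = np.triu_indices(len(driver_genes), k=1)
    link = linkage(np.maximum(dist[iu], 0.0), method="average")
    clusters = fcluster(link, t=k, criterion="maxclust")

    t_half = _half_activation_time(sm, times)
    order = (
        pd.DataFrame({"cluster": clusters, "t_half": t_half})
        .groupby("cluster")["t_half"]
        .mean()
        .sort_values()
        .index.tolist()
    )
    labels = {c: PHASES[min(i, len(PHASES) - 1)] for i, c in enumerate(order)}
    return pd.DataFrame(
        {
            "gene_id": driver_genes,
            "phase": [labels[c] for c in clusters],
            "t_half": t_half,
        }
    )


def call_primed_genes(
    normalized: FeatureMatrix,
    meta: pd.DataFrame,
    root_cluster: str,
    downstream_clusters: Sequence[str],
    downstream_upregulated: Mapping[str, Sequence[str]],
    disease_up_genes: Sequence[str],
    peak_counts: CountMatrix,
    peaks: pd.DataFrame,
    genes: pd.DataFrame,
    cfg: AnalysisConfig | None = None,
) -> pd.DataFrame:
    """Four-criterion primed-gene caller.

    A gene is primed iff (1) it is detected in fewer than ``inactive_pct`` of
    root-cluster cells in BOTH conditions; (2) it is an upregulated marker of
    at least one downstream cluster; (3) it is upregulated in the disease-vs-
    healthy contrast; and (4) at least one promoter peak (within
    ``promoter_halfwidth`` of the TSS) has root-cluster pseudo-bulk
    accessibility above the median dataset-wide per-peak accessibility.
    """
    cfg = cfg or AnalysisConfig()
    if root_cluster not in set(meta["cluster_label"]):
        raise ValueError(f"root cluster {root_cluster!r} absent from labels")
    peaks = peaks.reset_index(drop=True)
    genes = genes.reset_index(drop=True)
    cell_idx = normalized.cell_index()
    meta = meta.set_index("cell_id").loc[list(normalized.cell_ids)].reset_index()
    X = normalized.dense()

    # criterion 1: root-inactive in both conditions
    root_mask = (meta["cluster_label"] == root_cluster).to_numpy()
    disease_mask = is_disease(meta["condition"])
    detect = {}
    for cond_name, cond_mask in (("healthy", ~disease_mask), ("disease", disease_mask)):
        m = root_mask & cond_mask
        detect[cond_name] = (X[:, m] > 0).mean(axis=1) if m.any() else np.zeros(X.shape[0])
    root_inactive = (detect["healthy"] < cfg.inactive_pct) & (
        detect["disease"] < cfg.inactive_pct
    )

    # criterion 2: upregulated in >= 1 downstream cluster
    later = set()
    for cl in downstream_clusters:
        later |= set(downstream_upregulated.get(cl, []))
    later_activated = np.array([g in later for g in normalized.feature_ids])

    # criterion 3: disease-upregulated
    disease_up = np.array([g in set(disease_up_genes) for g in normalized.feature_ids])

    # criterion 4: open promoter in the root pseudo-bulk
    acc = peak_counts.values.astype(float)
    totals = np.asarray(acc.sum(axis=0)).ravel()
    totals[totals == 0] = 1.0
    acc_norm = np.asarray(acc.multiply(1e4 / totals).todense())
    atac_meta = meta.set_index("cell_id").loc[list(peak_counts.cell_ids)]
    root_atac = (atac_meta["cluster_label"] == root_cluster).to_numpy()
    root_acc = acc_norm[:, root_atac].mean(axis=1)
    overall_acc = acc_norm.mean(axis=1)
    open_threshold = float(np.median(overall_acc))

    peak_names = (
        peaks["name"].to_numpy(dtype=object) if "name" in peaks.columns
        else np.array([f"{c}:{s}-{e}" for c, s, e in
                       zip(peaks["chrom"], peaks["start"], peaks["end"])], dtype=object)
    )
    name_to_row = pd.Index(peak_counts.feature_ids)
    promoter_open = np.zeros(X.shape[0], dtype=bool)
    gene_pos = pd.Index(normalized.feature_ids)
    peak_center = (peaks["start"].to_numpy() + peaks["end"].to_numpy()) / 2.0
    for c in pd.unique(genes["chrom"]):
        psel = np.flatnonzero(peaks["chrom"].to_numpy() == c)
        if not len(psel):
            continue
        centers = peak_center[psel]
        order = np.argsort(centers)
        centers_sorted, psel_sorted = centers[order], psel[order]
        for _, g in genes[genes["chrom"] == c].iterrows():
            gi = gene_pos.get_indexer([g["gene_id"]])[0]
            if gi < 0:
                continue
            lo = np.searchsorted(centers_sorted, g["tss"] - cfg.promoter_halfwidth, "left")
            hi = np.searchsorted(centers_sorted, g["tss"] + cfg.promoter_halfwidth, "right")
            for pj in psel_sorted[lo:hi]:
                row = name_to_row.get_indexer([peak_names[pj]])[0]
                if row >= 0 and root_acc[row] > open_threshold:
                    promoter_open[gi] = True
                    break

    out = pd.DataFrame(
        {
            "gene_id": normalized.feature_ids,
            "root_inactive": root_inactive,
            "later_activated": later_activated,
            "disease_up": disease_up,
            "promoter_open_in_root": promoter_open,
        }
    )
    out["primed"] = (
        out["root_inactive"] & out["later_activated"]
        & out["disease_up"] & out["promoter_open_in_root"]
    )
    logger.info("[priming] %d primed genes", int(out["primed"].sum()))
    return out


def primed_tf_regulation(
    primed_genes: Sequence[str],
    grn: pd.DataFrame,
    regulator_tfs: Sequence[str],
    disease_up_genes: Sequence[str] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """TF x primed-gene regulation matrix with per-TF percentages.

    Entry (TF, g) = 1 iff the disease-filtered GRN contains >= 1 link TF->g.
    The per-TF percentage is 100 * row sum / number of primed genes; when a
    disease-upregulated background is supplied, a hypergeometric enrichment of
    each TF's targets within the primed set is added.
    """
    primed_genes = list(dict.fromkeys(primed_genes))
    if not primed_genes:
        raise ValueError("empty primed gene set")
    sub = grn[grn["tf_id"].isin(set(regulator_tfs))]
    targets = {tf: set(s["gene_id"]) for tf, s in sub.groupby("tf_id")}
    mat = pd.DataFrame(
        {
            tf: [int(g in targets.get(tf, set())) for g in primed_genes]
            for tf in regulator_tfs
        },
        index=primed_genes,
    ).T
    summary = pd.DataFrame(
        {
            "tf_id": list(regulator_tfs),
            "n_regulated": mat.sum(axis=1).to_numpy(),
        }
    )
    summary["pct_regulated"] = 100.0 * summary["n_regulated"] / len(primed_genes)
    if disease_up_genes is not None:
        bg = list(dict.fromkeys(disease_up_genes))
        N = len(bg)
        n_draw = len(set(primed_genes) & set(bg))
        pvals = []
        for tf in regulator_tfs:
            K = len(targets.get(tf, set()) & set(bg))
            k = len(targets.get(tf, set()) & set(primed_genes) & set(bg))
            pvals.append(float(stats.hypergeom.sf(k - 1, N, K, n_draw)) if N else 1.0)
        summary["enrichment_p"] = pvals
    return mat, summary
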