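"""Peak-to-gene links, condition classification, and the disease-filtered GRN.

Links are Pearson correlations between peak accessibility and gene expression
computed across pseudo-cell aggregates (random balanced groups within
cluster x condition) to tame single-cell sparsity; a peak and gene are
evaluated only when the peak center lies within the link window of the TSS.
TF->gene regulatory links fan out links through the motif annotation, and the
disease GRN keeps only disease-upregulated genes connected through
disease-opened peaks.
"""

from __future__ import annotations

import logging
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .config import AnalysisConfig
from .core import CountMatrix, FeatureMatrix
from .motifs import MotifAnnotation

logger = logging.getLogger("sfmultiome.linkage")


def make_pseudocells(
    meta: pd.DataFrame, n_pseudo: int = 100, seed: int = 1
) -> pd.Series:
    """Assign cells to ~n_pseudo aggregates, balanced within cluster x condition.

    Each cluster x condition stratum receives a share of the aggregates
    proportional to its size (at least one), and its cells are randomly and
    evenly split among them. Returns a cell_id-indexed aggregate label series.
    """
    rng = np.random.default_rng(seed)
    strata = meta.groupby(["cluster_label", "condition"], observed=True)
    sizes = strata.size()
    shares = np.maximum(1, np.round(n_pseudo * sizes / sizes.sum()).astype(int))
    labels = pd.Series(index=meta["cell_id"], dtype=object)
    agg_id = 0
    for (key, sub), k in zip(strata, shares):
        cells = sub["cell_id"].to_numpy().copy()
        rng.shuffle(cells)
        for i, chunk in enumerate(np.array_split(cells, k)):
            labels.loc[chunk] = f"agg{agg_id + i}"
        agg_id += k
    return labels


def _aggregate(M: np.ndarray, groups: np.ndarray) -> tuple[np.ndarray, list]:
    keys = list(pd.unique(groups))
    out = np.column_stack([M[:, groups == k].mean(axis=1) for k in keys])
    return out, keys


def _depth_normalize(counts: CountMatrix) -> np.ndarray:
    X = counts.values.astype(float)
    totals = np.asarray(X.sum(axis=0)).ravel()
    totals[totals == 0] = 1.0
    return np.asarray(X.multiply(1e4 / totals).todense())


def peak2gene_links(
    peak_counts: CountMatrix,
    normalized_expression: FeatureMatrix,
    peaks: pd.DataFrame,
    genes: pd.DataFrame,
    meta: pd.DataFrame,
    cfg: AnalysisConfig | None = None,
    cells: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Call peak-to-gene links on (optionally condition-restricted) cells.

    For every peak-gene pair with |peak center - TSS| <= link_window, Pearson r
    across pseudo-cell aggregates with a t-transform p and BH FDR; pairs with
    r >= link_r_min and fdr < link_fdr are kept. Constant vectors are skipped.
    """
    cfg = cfg or AnalysisConfig()
    peaks = peaks.reset_index(drop=True)
    genes = genes.reset_index(drop=True)
    if cells is not None:
        meta = meta[meta["cell_id"].isin(set(cells))]
    cell_ids = meta["cell_id"].tolist()
    pk = peak_counts.subset_cells(cell_ids)
    ex = normalized_expression.subset_cells(cell_ids)

    agg_labels = make_pseudocells(meta, cfg.n_pseudo, cfg.seed)
    groups = agg_labels.loc[cell_ids].to_numpy()
    P, _ = _aggregate(_depth_normalize(pk), groups)
    E, _ = _aggregate(ex.dense(), groups)
    n = P.shape[1]
    if n < 4:
        raise ValueError("too few aggregates for correlation")

    # candidate pairs by window
    peak_center = (peaks["start"].to_numpy() + peaks["end"].to_numpy()) / 2.0
    pairs_g, pairs_p = [], []
    for c in pd.unique(genes["chrom"]):
        gsel = np.flatnonzero(genes["chrom"].to_numpy() == c)
        psel = np.flatnonzero(peaks["chrom"].to_numpy() == c)
        if not len(gsel) or not len(psel):
            continue
        centers = peak_center[psel]
        order = np.argsort(centers)
        centers_sorted = centers[order]
        psel_sorted = psel[order]
        for gi in gsel:
            tss = float(genes["tss"].iloc[gi])
            lo = np.searchsorted(centers_sorted, tss - cfg.link_window, side="left")
            hi = np.searchsorted(centers_sorted, tss + cfg.link_window, side="right")
            for pj in psel_sorted[lo:hi]:
                pairs_g.append(gi)
                pairs_p.append(pj)
    if not pairs_g:
        return pd.DataFrame(
            columns=["peak", "gene_id", "pearson_r", "p", "fdr"]
        )
    pairs_g = np.asarray(pairs_g)
    pairs_p = np.asarray(pairs_p)

    def zscore(M):
        mu = M.mean(axis=1, keepdims=True)
        sd = M.std(axis=1, ddof=1, keepdims=True)
        ok = sd.ravel() > 0
        Z = np.zeros_like(M)
        Z[ok] = (M[ok] - mu[ok]) / sd[ok]
        return Z, ok

    Pz, p_ok = zscore(P)
    Ez, e_ok = zscore(E)
    valid = p_ok[pairs_p] & e_ok[pairs_g]
    r = np.einsum("ij,ij->i", Pz[pairs_p], Ez[pairs_g]) / (n - 1)
    r = np.clip(r, -1.0, 1.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        t = r * np.sqrt((n - 2) / np.maximum(1e-300, 1 - r**2))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)

    peak_names = (
        peaks["name"].to_numpy(dtype=object)
        if "name" in peaks.columns
        else np.array([f"{c}:{s}-{e}" for c, s, e in
                       zip(peaks["chrom"], peaks["start"], peaks["end"])], dtype=object)
    )
    out = pd.DataFrame(
        {
            "peak": peak_names[pairs_p],
            "gene_id": genes["gene_id"].to_numpy(dtype=object)[pairs_g],
            "pearson_r": r,
            "p": p,
        }
    )[valid].reset_index(drop=True)
    out["fdr"] = multipletests(out["p"], method="fdr_bh")[1] if len(out) else []
    kept = out[(out["pearson_r"] >= cfg.link_r_min) & (out["fdr"] < cfg.link_fdr)]
    logger.info("[links] %d candidate pairs -> %d links", len(pairs_g), len(kept))
    return kept.reset_index(drop=True)


def classify_links(
    links_healthy: pd.DataFrame, links_disease: pd.DataFrame
) -> pd.DataFrame:
    """Set algebra on (peak, gene) keys: shared / disease_only / healthy_only."""
    key = ["peak", "gene_id"]
    h = set(map(tuple, links_healthy[key].to_numpy()))
    d = set(map(tuple, links_disease[key].to_numpy()))
    rows = []
    for peak, gene in sorted(h | d):
        if (peak, gene) in h and (peak, gene) in d:
            cls = "shared"
        elif (peak, gene) in d:
            cls = "disease_only"
        else:
            cls = "healthy_only"
        rows.append((peak, gene, cls))
    out = pd.DataFrame(rows, columns=["peak", "gene_id", "condition_class"])
    counts = out["condition_class"].value_counts().to_dict()
    logger.info("[links] classified: %s", counts)
    return out


def tf_gene_links(
    links: pd.DataFrame, annotation: MotifAnnotation, tf_ids: Sequence[str] | None = None
) -> pd.DataFrame:
    """One (TF, peak, gene) regulatory link per motif-annotated linked peak."""
    tf_ids = list(tf_ids) if tf_ids is not None else list(annotation.motif_ids)
    peak_idx = pd.Index(annotation.peak_names)
    rows = []
    for tf in tf_ids:
        tf_peaks = set(annotation.peaks_for(tf))
        sub = links[links["peak"].isin(tf_peaks)]
        for link in sub.itertuples(index=False):
            rows.append((tf, link.peak, link.gene_id))
    return pd.DataFrame(rows, columns=["tf_id", "peak", "gene_id"])


def filter_disease_grn(
    links: pd.DataFrame,
    disease_up_genes: Sequence[str],
    disease_open_peaks: Sequence[str],
) -> pd.DataFrame:
    """Keep links whose gene is disease-upregulated AND peak disease-opened."""
    up = set(disease_up_genes)
    open_ = set(disease_open_peaks)
    out = links.copy()
    out["passes_disease_filter"] = out["gene_id"].isin(up) & out["peak"].isin(open_)
    kept = out[out["passes_disease_filter"]].reset_index(drop=True)
    logger.info("[grn] %d / %d links pass the disease filter", len(kept), len(out))
    return kept


def tf_target_sets(grn: pd.DataFrame) -> dict[str, set]:
    return {tf: set(sub["gene_id"]) for tf, sub in grn.groupby("tf_id")}
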