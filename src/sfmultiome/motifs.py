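"""Motif annotation, per-cell motif deviations, enrichment, and positive regulators.

Deviations follow the chromVAR recipe: for motif m and cell c the expected
accessibility is the depth-scaled share of the motif's peaks in the total
signal; the raw deviation is (observed - expected) / expected, and the z-score
standardizes the raw deviation against accessibility-matched background peak
sets. Positive TF regulators are TFs whose motif deviation correlates
positively with their own expression (Pearson r^2 > 0.5, BH-adjusted p < 0.05).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .config import AnalysisConfig
from .core import CountMatrix, FeatureMatrix, validate_intervals

logger = logging.getLogger("sfmultiome.motifs")


@dataclass
class MotifAnnotation:
    """Binary motifs x peaks membership matrix."""

    motif_ids: np.ndarray
    peak_names: np.ndarray
    matrix: sp.csr_matrix  # bool/int {0,1}

    def peaks_for(self, motif_id: str) -> np.ndarray:
        row = int(np.flatnonzero(self.motif_ids == motif_id)[0])
        return self.peak_names[self.matrix[row].indices]


@dataclass
class DeviationMatrix:
    motif_ids: np.ndarray
    cell_ids: np.ndarray
    z: np.ndarray            # motifs x cells deviation z-scores
    raw: np.ndarray          # motifs x cells raw deviations
    n_background: int

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.z, index=self.motif_ids, columns=self.cell_ids)


def annotate_motifs(peaks: pd.DataFrame, motif_hits: pd.DataFrame) -> MotifAnnotation:
    """entry(m, p) = 1 iff any hit of motif m overlaps peak p by >= 1 bp.

    Peaks must be non-overlapping (the merged peak set); overlap uses the
    half-open convention, so a hit abutting a peak end does not count.
    """
    peaks = validate_intervals(peaks, "peak").reset_index(drop=True)
    validate_intervals(motif_hits, "motif hit")
    motif_ids = np.asarray(pd.unique(motif_hits["name"]), dtype=object)
    motif_pos = pd.Index(motif_ids)
    rows, cols = [], []
    for c, sub in peaks.groupby("chrom", sort=False):
        starts = sub["start"].to_numpy()
        ends = sub["end"].to_numpy()
        order = np.argsort(starts)
        starts, ends = starts[order], ends[order]
        orig = sub.index.to_numpy()[order]
        hits = motif_hits[motif_hits["chrom"] == c]
        if not len(hits):
            continue
        hs = hits["start"].to_numpy()
        he = hits["end"].to_numpy()
        hm = motif_pos.get_indexer(hits["name"])
        # candidate peak: last peak starting strictly before hit end
        j = np.searchsorted(starts, he - 1, side="right") - 1
        ok = (j >= 0) & (hs < ends[np.clip(j, 0, None)])
        rows.extend(hm[ok].tolist())
        cols.extend(orig[j[ok]].tolist())
    mat = sp.coo_matrix(
        (np.ones(len(rows)), (rows, cols)), shape=(len(motif_ids), len(peaks))
    ).tocsr()
    mat.data = np.minimum(mat.data, 1.0)
    empty = np.flatnonzero(np.asarray(mat.sum(axis=1)).ravel() == 0)
    for i in empty:
        logger.warning("[motifs] motif %s annotates no peak", motif_ids[i])
    names = peaks["name"].to_numpy(dtype=object) if "name" in peaks.columns else np.array(
        [f"{c}:{s}-{e}" for c, s, e in zip(peaks["chrom"], peaks["start"], peaks["end"])],
        dtype=object,
    )
    return MotifAnnotation(motif_ids, names, mat)


def sample_background_peaks(
    peak_counts: CountMatrix,
    n_background: int = 50,
    n_bins: int = 10,
    seed: int = 1,
) -> np.ndarray:
    """Accessibility-matched background peaks, ``n_peaks x n_background``.

    Peaks are stratified into ``n_bins`` quantile bins of mean accessibility
    (GC matching is skipped when no sequence is available); each peak's
    backgrounds are drawn with replacement from its stratum. A stratum of size
    1 falls back to the nearest nonempty stratum with a warning.
    """
    rng = np.random.default_rng(seed)
    mean_acc = np.asarray(peak_counts.values.mean(axis=1)).ravel()
    n_peaks = len(mean_acc)
    # quantile binning; duplicate edges collapse strata gracefully
    quantiles = np.quantile(mean_acc, np.linspace(0, 1, n_bins + 1))
    edges = np.unique(quantiles)
    bins = np.clip(np.searchsorted(edges, mean_acc, side="right") - 1, 0, len(edges) - 2)
    out = np.empty((n_peaks, n_background), dtype=np.int64)
    for b in np.unique(bins):
        members = np.flatnonzero(bins == b)
        pool = members
        if len(pool) == 1:
            logger.warning("[motifs] background stratum %d has a single peak; "
                           "falling back to nearest stratum", b)
            dist = np.abs(bins - b)
            dist[members] = np.iinfo(np.int64).max
            nearest = np.flatnonzero(dist == dist.min())
            pool = np.concatenate([members, nearest])
        out[members] = rng.choice(pool, size=(len(members), n_background), replace=True)
    return out


def motif_deviations(
    peak_counts: CountMatrix,
    annotation: MotifAnnotation,
    backgrounds: np.ndarray,
) -> DeviationMatrix:
    """chromVAR-style raw deviations and background-standardized z-scores."""
    X = peak_counts.values.astype(float).tocsr()
    peak_totals = np.asarray(X.sum(axis=1)).ravel()
    cell_totals = np.asarray(X.sum(axis=0)).ravel()
    if (cell_totals == 0).any():
        bad = peak_counts.cell_ids[np.flatnonzero(cell_totals == 0)[0]]
        raise ValueError(f"cell with zero peak counts: {bad!r}")
    grand = peak_totals.sum()

    A = annotation.matrix.astype(float)

    def raw_dev(membership: sp.csr_matrix) -> np.ndarray:
        obs = np.asarray((membership @ X).todense())
        frac = np.asarray(membership @ peak_totals).ravel() / grand
        expected = np.outer(frac, cell_totals)
        if (expected == 0).any():
            zero = annotation.motif_ids[np.flatnonzero(expected.sum(axis=1) == 0)]
            raise ValueError(f"motif with zero expected accessibility: {zero[:3]}")
        return obs / expected - 1.0

    raw = raw_dev(A)

    n_bg = backgrounds.shape[1]
    s = np.zeros_like(raw)
    s2 = np.zeros_like(raw)
    indptr, indices, data = A.indptr, A.indices, A.data
    for j in range(n_bg):
        # background membership: replace each motif peak by its j-th match;
        # duplicates accumulate, mirroring sampling with replacement
        bg_indices = backgrounds[indices, j]
        Bj = sp.csr_matrix(
            (data, bg_indices, indptr), shape=A.shape
        )
        Bj.sum_duplicates()
        dj = raw_dev(Bj)
        s += dj
        s2 += dj * dj
    mean_bg = s / n_bg
    var_bg = np.maximum(s2 / n_bg - mean_bg**2, 0.0)
    sd_bg = np.sqrt(var_bg * n_bg / max(n_bg - 1, 1))
    with np.errstate(invalid="ignore", divide="ignore"):
        z = np.where(sd_bg > 0, (raw - mean_bg) / sd_bg, 0.0)
    if (sd_bg == 0).any():
        logger.warning("[motifs] %d deviation entries had zero background sd; "
                       "z set to 0", int((sd_bg == 0).sum()))
    return DeviationMatrix(
        annotation.motif_ids, peak_counts.cell_ids, z, raw, n_bg
    )


def motif_enrichment(
    marker_peaks: Sequence[str],
    annotation: MotifAnnotation,
    cfg: AnalysisConfig | None = None,
) -> pd.DataFrame:
    """Hypergeometric enrichment of each motif within a marker-peak set.

    Universe = all annotated peaks; upper-tail p of motif-bearing peaks among
    the markers; BH adjustment across motifs; motifs passing the adjusted
    cutoff are flagged.
    """
    cfg = cfg or AnalysisConfig()
    marker_peaks = set(marker_peaks)
    if not marker_peaks:
        raise ValueError("empty marker peak set")
    unknown = marker_peaks - set(annotation.peak_names)
    if unknown:
        raise ValueError(f"marker peaks not in universe: {sorted(unknown)[:5]}")
    in_markers = np.array([p in marker_peaks for p in annotation.peak_names])
    N = len(annotation.peak_names)
    n_draw = int(in_markers.sum())
    A = annotation.matrix
    motif_total = np.asarray(A.sum(axis=1)).ravel().astype(int)
    motif_in_markers = np.asarray(A[:, np.flatnonzero(in_markers)].sum(axis=1)).ravel().astype(int)
    p = stats.hypergeom.sf(motif_in_markers - 1, N, motif_total, n_draw)
    out = pd.DataFrame(
        {
            "motif_id": annotation.motif_ids,
            "overlap": motif_in_markers,
            "motif_peaks": motif_total,
            "marker_peaks": n_draw,
            "universe": N,
            "p": p,
        }
    )
    out["p_adj"] = multipletests(out["p"], method="fdr_bh")[1]
    out["enriched"] = out["p_adj"] < cfg.motif_p
    return out.sort_values("p_adj").reset_index(drop=True)


def _group_means(M: np.ndarray, groups: np.ndarray) -> tuple[np.ndarray, list]:
    keys = pd.unique(groups)
    means = np.column_stack([M[:, groups == k].mean(axis=1) for k in keys])
    return means, list(keys)


def positive_regulators(
    deviations: DeviationMatrix,
    normalized_expression: FeatureMatrix,
    tf_ids: Sequence[str],
    grouping: np.ndarray | None = None,
    cfg: AnalysisConfig | None = None,
) -> pd.DataFrame:
    """Detect positive TF regulators.

    Pearson correlation between a TF's motif deviation z-scores and its own
    normalized expression is computed across per-group means (default) or per
    cell when ``grouping`` is None; TFs with r > 0, r^2 > r2_min and BH-adjusted
    p < reg_padj are flagged ``positive``. Constant vectors are skipped with a
    warning.
    """
    cfg = cfg or AnalysisConfig()
    dev_idx = pd.Index(deviations.motif_ids)
    expr_idx = normalized_expression.feature_index()
    cells_dev = pd.Index(deviations.cell_ids)
    cells_expr = normalized_expression.cell_index()
    common_cells = cells_dev.intersection(cells_expr)
    Z = deviations.z[:, cells_dev.get_indexer(common_cells)]
    E = normalized_expression.dense()[:, cells_expr.get_indexer(common_cells)]

    if grouping is not None:
        grouping = np.asarray(grouping, dtype=object)
        Z, _ = _group_means(Z, grouping)
        E, _ = _group_means(E, grouping)
    n = Z.shape[1]

    rows = []
    for tf in tf_ids:
        if tf not in dev_idx or tf not in expr_idx:
            raise KeyError(f"TF {tf!r} missing from deviations or expression")
        z = Z[dev_idx.get_loc(tf)]
        e = E[expr_idx.get_loc(tf)]
        if np.std(z) == 0 or np.std(e) == 0:
            logger.warning("[regulators] TF %s has constant vector; skipped", tf)
            continue
        r, p = stats.pearsonr(z, e)
        rows.append((tf, r, r * r, p, n))
    out = pd.DataFrame(rows, columns=["tf_id", "pearson_r", "r_squared", "p", "n_units"])
    if len(out):
        out["p_adj"] = multipletests(out["p"], method="fdr_bh")[1]
        out["positive"] = (
            (out["pearson_r"] > 0)
            & (out["r_squared"] > cfg.r2_min)
            & (out["p_adj"] < cfg.reg_padj)
        )
    else:
        out["p_adj"] = []
        out["positive"] = []
    return out.sort_values("r_squared", ascending=False).reset_index(drop=True)
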