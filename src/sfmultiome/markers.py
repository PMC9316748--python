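"""scRNA QC, normalization, Wilcoxon marker detection, and over-representation.

Thresholds follow the study design: cells with fewer than 500 detected genes or
more than 10% mitochondrial reads are excluded (boundary values retained);
normalization is ln(1 + 10,000 * count / cell_total); markers use a two-sided
Wilcoxon rank-sum test with Bonferroni correction over all features, excluding
genes detected in < 25% of cells in both groups or with |avgLFC| < 0.25; the
over-representation test is hypergeometric with BH adjustment, reporting sets
at adjusted p < 0.05 with overlap >= 3.
"""

from __future__ import annotations

import logging
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .config import AnalysisConfig
from .core import CountMatrix, FeatureMatrix

logger = logging.getLogger("sfmultiome.markers")

LN2 = float(np.log(2.0))


# ---------------------------------------------------------------------------
# QC

def compute_qc(expression: CountMatrix, mito_prefix: str = "mt-") -> pd.DataFrame:
    """Per-cell detected-feature counts and % mitochondrial reads.

    Mitochondrial genes are identified by a configurable id prefix
    (case-insensitive), matching common annotation conventions.
    """
    X = expression.values.tocsc()
    n_detected = np.asarray((X > 0).sum(axis=0)).ravel()
    totals = np.asarray(X.sum(axis=0)).ravel().astype(float)
    is_mito = np.array(
        [str(g).lower().startswith(mito_prefix.lower()) for g in expression.feature_ids]
    )
    mito = np.asarray(X[is_mito].sum(axis=0)).ravel() if is_mito.any() else np.zeros_like(totals)
    with np.errstate(invalid="ignore", divide="ignore"):
        pct_mito = np.where(totals > 0, 100.0 * mito / totals, 0.0)
    return pd.DataFrame(
        {"cell_id": expression.cell_ids, "n_features_detected": n_detected,
         "pct_mito": pct_mito}
    )


def filter_cells(
    expression: CountMatrix, meta: pd.DataFrame, cfg: AnalysisConfig
) -> list[str]:
    """Retain cells with >= min_genes detected AND <= max_pct_mito.

    The exclusion rule is "less than 500 genes or more than 10%", so exactly
    500 genes and exactly 10.0% are retained.
    """
    qc = compute_qc(expression, cfg.mito_prefix).set_index("cell_id")
    cells = meta["cell_id"].tolist()
    qc = qc.loc[cells]
    keep = (qc["n_features_detected"] >= cfg.min_genes) & (
        qc["pct_mito"] <= cfg.max_pct_mito
    )
    retained = [c for c, k in zip(cells, keep) if k]
    if not retained:
        raise ValueError("empty dataset after QC")
    logger.info("[qc] retained %d / %d cells", len(retained), len(cells))
    return retained


# ---------------------------------------------------------------------------
# normalization

def normalize_expression(
    expression: CountMatrix, cfg: AnalysisConfig | None = None
) -> FeatureMatrix:
    """Library-size normalize and log-transform: ln(1 + sf * count / total)."""
    sf = cfg.scale_factor if cfg is not None else 10_000.0
    X = expression.values.tocsc().astype(float)
    totals = np.asarray(X.sum(axis=0)).ravel()
    if (totals == 0).any():
        bad = expression.cell_ids[np.flatnonzero(totals == 0)[0]]
        raise ValueError(f"all-zero cell: {bad!r}")
    X = X.multiply(sf / totals).tocsr()
    X.data = np.log1p(X.data)
    return FeatureMatrix(expression.feature_ids, expression.cell_ids, X)


# ---------------------------------------------------------------------------
# Wilcoxon rank-sum machinery

def _ranksum_exact_p(x: np.ndarray, y: np.ndarray) -> float:
    # Exact two-sided p: min(1, 2 * min(P(U <= u), P(U >= u))) over the exact
    # null distribution of the Mann-Whitney U statistic (valid without ties).
    return float(
        stats.mannwhitneyu(x, y, alternative="two-sided", method="exact").pvalue
    )


def _ranksum_asymptotic(
    X: np.ndarray, mask: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized two-sided rank-sum test with tie correction.

    Returns (U, p) per row of ``X`` for group = ``mask`` vs rest, using the
    normal approximation with continuity correction.
    """
    n1 = int(mask.sum())
    n2 = int((~mask).sum())
    n = n1 + n2
    ranks = stats.rankdata(X, axis=1)
    rank_sum = ranks[:, mask].sum(axis=1)
    U = rank_sum - n1 * (n1 + 1) / 2.0
    mu = n1 * n2 / 2.0
    # tie correction per feature
    tie_term = np.zeros(X.shape[0])
    for i in range(X.shape[0]):
        _, counts = np.unique(X[i], return_counts=True)
        tie_term[i] = np.sum(counts**3 - counts)
    sigma2 = n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    sigma = np.sqrt(sigma2)
    with np.errstate(invalid="ignore", divide="ignore"):
        z = (U - mu - 0.5 * np.sign(U - mu)) / sigma
    p = np.where(sigma > 0, 2.0 * stats.norm.sf(np.abs(z)), 1.0)
    return U, np.minimum(p, 1.0)


def ranksum_p(x: np.ndarray, y: np.ndarray, exact_max_n: int = 25) -> float:
    """Two-sided Wilcoxon rank-sum p for one feature.

    Exact enumeration when both groups have <= ``exact_max_n`` observations and
    there are no ties; normal approximation with tie correction otherwise.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    pooled = np.concatenate([x, y])
    no_ties = len(np.unique(pooled)) == len(pooled)
    if len(x) <= exact_max_n and len(y) <= exact_max_n and no_ties:
        return _ranksum_exact_p(x, y)
    X = pooled[None, :]
    mask = np.zeros(len(pooled), dtype=bool)
    mask[: len(x)] = True
    _, p = _ranksum_asymptotic(X, mask)
    return float(p[0])


def _avg_lfc(norm_group: np.ndarray, norm_rest: np.ndarray) -> np.ndarray:
    # Seurat-style fold change on the normalized scale, natural log to match
    # the ln-based normalization.
    mean_g = np.expm1(norm_group).mean(axis=1)
    mean_r = np.expm1(norm_rest).mean(axis=1)
    return np.log1p(mean_g) - np.log1p(mean_r)


def find_markers(
    normalized: FeatureMatrix,
    labels: Sequence[str] | np.ndarray,
    group: str | np.ndarray,
    cfg: AnalysisConfig | None = None,
    *,
    lfc_base: str = "e",
    exact_max_n: int = 25,
    marker_filters: bool = True,
) -> pd.DataFrame:
    """Differential features for ``group`` vs rest.

    Emits avgLFC, two-sided rank-sum p, Bonferroni p_adj over all features in
    the matrix, and detection fractions; with ``marker_filters`` (the marker-
    detection convention), features with pct1 < pct_min AND pct2 < pct_min, or
    |avgLFC| < lfc_min, are excluded from the output. Differential peak
    accessibility disables these exclusions and applies only its own log2FC/p
    cutoffs downstream. ``lfc_base`` = "2" reports the fold change in log2.
    """
    cfg = cfg or AnalysisConfig()
    labels = np.asarray(labels, dtype=object)
    if isinstance(group, (str, np.str_)):
        mask = labels == group
        group_label = str(group)
    else:
        mask = np.asarray(group, dtype=bool)
        group_label = "group"
    if mask.sum() < 3 or (~mask).sum() < 3:
        raise ValueError("each group must contain at least 3 cells")

    X = normalized.dense()
    n_features = X.shape[0]
    Xg, Xr = X[:, mask], X[:, ~mask]
    pct1 = (Xg > 0).mean(axis=1)
    pct2 = (Xr > 0).mean(axis=1)
    lfc = _avg_lfc(Xg, Xr)
    if lfc_base == "2":
        lfc = lfc / LN2

    if marker_filters:
        keep = ~((pct1 < cfg.pct_min) & (pct2 < cfg.pct_min))
        keep &= np.abs(lfc) >= cfg.lfc_min
    else:
        keep = np.ones(n_features, dtype=bool)

    p = np.ones(n_features)
    small = mask.sum() <= exact_max_n and (~mask).sum() <= exact_max_n
    idx = np.flatnonzero(keep)
    if small:
        for i in idx:
            p[i] = ranksum_p(Xg[i], Xr[i], exact_max_n=exact_max_n)
    elif len(idx):
        _, p[idx] = _ranksum_asymptotic(X[idx], mask)
    p_adj = np.minimum(1.0, p * n_features)

    out = pd.DataFrame(
        {
            "feature_id": normalized.feature_ids,
            "group_label": group_label,
            "avg_lfc": lfc,
            "p": p,
            "p_adj": p_adj,
            "pct1": pct1,
            "pct2": pct2,
        }
    )
    return out[keep].reset_index(drop=True)


def find_all_markers(
    normalized: FeatureMatrix,
    labels: Sequence[str] | np.ndarray,
    cfg: AnalysisConfig | None = None,
    **kwargs,
) -> pd.DataFrame:
    """One-vs-rest markers for every label, concatenated."""
    labels = np.asarray(labels, dtype=object)
    frames = []
    for lab in pd.unique(labels):
        res = find_markers(normalized, labels, lab, cfg, **kwargs)
        res["group_label"] = lab
        frames.append(res)
    return pd.concat(frames, ignore_index=True)


def select_upregulated(
    markers: pd.DataFrame, cfg: AnalysisConfig | None = None
) -> list[str]:
    """Upregulated features: unadjusted p < up_p and avgLFC >= lfc_min."""
    cfg = cfg or AnalysisConfig()
    sel = markers[(markers["p"] < cfg.up_p) & (markers["avg_lfc"] >= cfg.lfc_min)]
    return sel["feature_id"].drop_duplicates().tolist()


# ---------------------------------------------------------------------------
# over-representation analysis

def overrepresentation(
    gene_list: Sequence[str],
    background: Sequence[str],
    gene_sets: Mapping[str, Sequence[str]],
    cfg: AnalysisConfig | None = None,
) -> pd.DataFrame:
    """Hypergeometric over-representation of ``gene_list`` in each gene set.

    The background is the active-gene universe; sets are intersected with it
    before testing. Reported sets satisfy BH-adjusted p < 0.05 and overlap >= 3.
    """
    cfg = cfg or AnalysisConfig()
    background = set(background)
    if not background:
        raise ValueError("empty background")
    query = set(gene_list) & background
    if set(gene_list) - background:
        raise ValueError("gene_list must be a subset of background")
    rows = []
    for set_id, members in gene_sets.items():
        members = set(members) & background
        overlap = len(query & members)
        # upper tail: P(X >= overlap)
        p = stats.hypergeom.sf(overlap - 1, len(background), len(members), len(query))
        rows.append((set_id, overlap, len(members), len(query), len(background), p))
    out = pd.DataFrame(
        rows,
        columns=["set_id", "overlap_count", "set_size", "list_size",
                 "background_size", "p"],
    )
    if len(out):
        out["p_adj"] = multipletests(out["p"], method="fdr_bh")[1]
    else:
        out["p_adj"] = []
    reported = out[(out["p_adj"] < 0.05) & (out["overlap_count"] >= 3)]
    return reported.sort_values("p_adj").reset_index(drop=True)
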