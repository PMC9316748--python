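"""Regulon inference, AUC activity scoring, homolog mapping, and modules.

Regulons follow the SCENIC logic: candidate targets are ranked by a
co-expression importance (absolute Spearman correlation with the TF), the top
candidates are pruned to genes with motif evidence for that TF, and each
regulon's per-cell activity is a rank-based recovery AUC. Cross-species
analysis maps genes through a one-to-one homolog table, intersects regulons
between species, and clusters conserved TFs into modules by the correlation of
their motif deviations.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage

from .core import FeatureMatrix
from .motifs import DeviationMatrix

logger = logging.getLogger("sfmultiome.regulons")


@dataclass
class Regulon:
    tf_id: str
    targets: list[str]
    importance: dict[str, float] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# homolog mapping

def resolve_homologs(table: pd.DataFrame) -> pd.DataFrame:
    """Drop every many-to-many pair, keeping a strict one-to-one table.

    ``table`` has two columns (species A id, species B id); any gene appearing
    in more than one pair, on either side, is removed with a log message.
    """
    a_col, b_col = table.columns[:2]
    dup_a = table[a_col][table[a_col].duplicated(keep=False)].unique()
    dup_b = table[b_col][table[b_col].duplicated(keep=False)].unique()
    keep = ~(table[a_col].isin(dup_a) | table[b_col].isin(dup_b))
    dropped = int((~keep).sum())
    if dropped:
        logger.info("[homologs] dropped %d ambiguous pairs", dropped)
    return table[keep].reset_index(drop=True)


def map_homologs(
    matrix: FeatureMatrix, table: pd.DataFrame, direction: str = "a_to_b"
) -> FeatureMatrix:
    """Rename matrix rows into the partner species' namespace.

    The table is resolved to one-to-one first; unmapped genes are dropped and
    a mapping report logged. An empty intersection raises.
    """
    table = resolve_homologs(table)
    a_col, b_col = table.columns[:2]
    if direction == "a_to_b":
        mapping = dict(zip(table[a_col], table[b_col]))
    elif direction == "b_to_a":
        mapping = dict(zip(table[b_col], table[a_col]))
    else:
        raise ValueError("direction must be 'a_to_b' or 'b_to_a'")
    keep = [i for i, g in enumerate(matrix.feature_ids) if g in mapping]
    if not keep:
        raise ValueError("no genes map through the homolog table")
    new_ids = np.asarray([mapping[matrix.feature_ids[i]] for i in keep], dtype=object)
    logger.info("[homologs] mapped %d / %d genes", len(keep), len(matrix.feature_ids))
    return type(matrix)(new_ids, matrix.cell_ids, matrix.values[keep, :])


# ---------------------------------------------------------------------------
# regulon inference

def infer_regulons(
    normalized: FeatureMatrix,
    tf_list: Sequence[str],
    motif_prior: Mapping[str, Sequence[str]],
    top_k: int = 200,
    min_targets: int = 10,
) -> list[Regulon]:
    """Co-expression grouping followed by motif pruning.

    Per TF, candidate targets are ranked by |Spearman correlation| with the TF
    across cells; the top ``top_k`` candidates are pruned to the TF's motif
    prior; regulons with fewer than ``min_targets`` surviving targets are
    discarded. TFs with constant expression are skipped with a warning.
    """
    gene_idx = normalized.feature_index()
    X = normalized.dense()
    # Spearman = Pearson on within-gene ranks
    R = stats.rankdata(X, axis=1)
    mu = R.mean(axis=1, keepdims=True)
    sd = R.std(axis=1, keepdims=True)
    constant = sd.ravel() == 0
    sd[sd == 0] = 1.0
    Z = (R - mu) / sd

    regulons = []
    for tf in tf_list:
        if tf not in gene_idx:
            raise KeyError(f"TF {tf!r} absent from expression matrix")
        ti = gene_idx.get_loc(tf)
        if constant[ti]:
            logger.warning("[regulons] TF %s has constant expression; skipped", tf)
            continue
        rho = (Z @ Z[ti]) / Z.shape[1]
        rho[ti] = 0.0  # the TF is not its own candidate
        rho[constant] = 0.0
        order = np.argsort(-np.abs(rho), kind="stable")[:top_k]
        prior = set(motif_prior.get(tf, ()))
        targets = [
            normalized.feature_ids[i] for i in order if normalized.feature_ids[i] in prior
        ]
        if len(targets) < min_targets:
            logger.info("[regulons] TF %s: only %d motif-supported targets; discarded",
                        tf, len(targets))
            continue
        regulons.append(
            Regulon(tf, targets, {normalized.feature_ids[i]: float(np.abs(rho[i]))
                                  for i in order})
        )
    return regulons


# ---------------------------------------------------------------------------
# AUC activity scoring

def score_regulon_auc(
    normalized: FeatureMatrix, regulon: Regulon | Sequence[str], top_frac: float = 0.05
) -> pd.Series:
    """Per-cell rank-based recovery AUC of a regulon, normalized to [0, 1].

    Genes are ranked per cell by descending expression (ties broken by stable
    gene order); the step recovery curve of regulon genes over the top
    ``ceil(top_frac * n_genes)`` ranks is integrated by the trapezoid rule and
    normalized by the maximal (all regulon genes at the very top) curve.
    """
    if not (0 < top_frac <= 0.5):
        raise ValueError("top_frac must lie in (0, 0.5]")
    targets = regulon.targets if isinstance(regulon, Regulon) else list(regulon)
    gene_idx = normalized.feature_index()
    member = np.asarray([g in set(targets) for g in normalized.feature_ids])
    m = int(member.sum())
    if m == 0:
        raise ValueError("regulon is disjoint from the matrix genes")
    X = normalized.dense()
    n_genes, n_cells = X.shape
    cutoff = int(np.ceil(top_frac * n_genes))

    # stable descending sort: argsort of -expression keeps gene order on ties
    order = np.argsort(-X, axis=0, kind="stable")
    top = order[:cutoff, :]                       # cutoff x cells gene indices
    hits = member[top]                            # bool cutoff x cells
    y = np.cumsum(hits, axis=0).astype(float)     # recovery curve per cell

    def trapezoid(curve: np.ndarray) -> np.ndarray:
        padded = np.vstack([np.zeros((1, curve.shape[1])), curve])
        return ((padded[1:] + padded[:-1]) / 2.0).sum(axis=0)

    auc = trapezoid(y)
    y_max = np.minimum(np.arange(1, cutoff + 1), min(m, cutoff)).astype(float)
    max_auc = float(
        (np.concatenate([[0.0], y_max])[1:] + np.concatenate([[0.0], y_max])[:-1]).sum()
        / 2.0
    )
    return pd.Series(auc / max_auc, index=normalized.cell_ids, name="auc")


def score_all_regulons(
    normalized: FeatureMatrix, regulons: Sequence[Regulon], top_frac: float = 0.05
) -> pd.DataFrame:
    return pd.DataFrame(
        {r.tf_id: score_regulon_auc(normalized, r, top_frac) for r in regulons}
    )


# ---------------------------------------------------------------------------
# conserved regulons and modules

def conserved_regulons(
    regulons_a: Sequence[Regulon],
    regulons_b: Sequence[Regulon],
    homolog_table: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """TFs with a regulon in both species, with merged target support.

    When a homolog table (columns: species A id, species B id) is given, the
    B-side TF and target names are mapped into the A namespace first. Reports
    the conserved target intersection and the per-TF Jaccard of target sets.
    """
    def as_dict(regs):
        return {r.tf_id: set(r.targets) for r in regs}

    a = as_dict(regulons_a)
    b = as_dict(regulons_b)
    if homolog_table is not None:
        table = resolve_homologs(homolog_table)
        a_col, b_col = table.columns[:2]
        b_to_a = dict(zip(table[b_col], table[a_col]))
        b = {
            b_to_a[tf]: {b_to_a[g] for g in targets if g in b_to_a}
            for tf, targets in b.items()
            if tf in b_to_a
        }
    shared = sorted(set(a) & set(b))
    rows = []
    for tf in shared:
        inter = a[tf] & b[tf]
        union = a[tf] | b[tf]
        rows.append(
            (tf, sorted(inter), len(a[tf]), len(b[tf]),
             len(inter) / len(union) if union else 0.0)
        )
    return pd.DataFrame(
        rows, columns=["tf_id", "conserved_targets", "n_targets_a", "n_targets_b",
                       "jaccard"]
    )


def cluster_regulon_modules(
    deviations: DeviationMatrix | pd.DataFrame,
    tf_ids: Sequence[str],
    k: int = 3,
    context: pd.Series | None = None,
) -> pd.DataFrame:
    """Cluster conserved TFs into regulatory modules.

    Pairwise Pearson correlation between TF deviation profiles, distance
    1 - r, average-linkage hierarchical clustering cut at ``k``. When a
    per-cell ``context`` labeling is given, each module is labeled by the
    context with the highest mean deviation over its TFs.
    """
    tf_ids = list(tf_ids)
    if k > len(tf_ids):
        raise ValueError(f"k={k} exceeds the {len(tf_ids)} supplied TFs")
    if isinstance(deviations, DeviationMatrix):
        frame = deviations.frame()
    else:
        frame = deviations
    D = frame.loc[tf_ids].to_numpy(dtype=float)
    Z = D - D.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(Z, axis=1, keepdims=True)
    norms[norms == 0] = 1.0
    corr = (Z / norms) @ (Z / norms).T
    dist = np.maximum(1.0 - corr, 0.0)
    iu = np.triu_indices(len(tf_ids), k=1)
    if len(tf_ids) > 1:
        clusters = fcluster(linkage(dist[iu], method="average"), t=k,
                            criterion="maxclust")
    else:
        clusters = np.array([1])
    out = pd.DataFrame({"tf_id": tf_ids, "module": clusters})
    if context is not None:
        labels = {}
        ctx = context.loc[frame.columns]
        for mod, sub in out.groupby("module"):
            mean_dev = pd.Series(
                D[out["module"].to_numpy() == mod].mean(axis=0), index=frame.columns
            )
            labels[mod] = str(mean_dev.groupby(ctx.to_numpy()).mean().idxmax())
        out["label"] = out["module"].map(labels)
    return out
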