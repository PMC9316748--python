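"""Tile counting, iterative-overlap peak merging, and gene activity scores.

The accessibility side of the pipeline: Tn5 insertion ends are counted in
genome-wide 500-bp tiles; candidate fixed-width peaks are reduced to a single
non-overlapping peak set by score-ranked iterative overlap removal, first per
pseudo-bulk replicate level and then across clusters; gene activity scores
aggregate tile counts within 100 kb of each TSS with the distance weight
``exp(-|d|/5000) + exp(-1)``, a gene-length factor mapping 1/length linearly
onto [1, 5], per-cell scaling to 10,000 and log2(1 + x).
"""

from __future__ import annotations

import logging
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .config import AnalysisConfig
from .core import CountMatrix, FeatureMatrix, validate_intervals

logger = logging.getLogger("sfmultiome.atac")


# ---------------------------------------------------------------------------
# tile counting

def tile_name(chrom: str, tile_idx: int, tile_width: int) -> str:
    start = tile_idx * tile_width
    return f"{chrom}:{start}-{start + tile_width}"


def count_tiles(
    fragments: pd.DataFrame,
    genome: Mapping[str, int],
    tile_width: int = 500,
    cell_ids: Sequence[str] | None = None,
) -> CountMatrix:
    """Count Tn5 insertions in genome-wide fixed-width tiles.

    ``fragments`` has columns (cell, chrom, start, end); both insertion ends of
    each fragment (positions ``start`` and ``end - 1``) are counted. Tiles with
    zero total are omitted from the sparse matrix. Insertions beyond the
    chromosome length raise.
    """
    if tile_width <= 0:
        raise ValueError("tile_width must be > 0")
    cells = (
        np.asarray(list(cell_ids), dtype=object)
        if cell_ids is not None
        else pd.unique(fragments["cell"].to_numpy())
    )
    cell_pos = pd.Index(cells).get_indexer(fragments["cell"])
    if (cell_pos < 0).any():
        raise ValueError("fragment cell absent from cell_ids")

    chroms = list(genome)
    chrom_idx = pd.Index(chroms).get_indexer(fragments["chrom"])
    if (chrom_idx < 0).any():
        bad = fragments["chrom"][chrom_idx < 0].iloc[0]
        raise ValueError(f"fragment chromosome {bad!r} absent from genome")
    lengths = np.array([genome[c] for c in chroms], dtype=np.int64)
    n_tiles_per_chrom = -(-lengths // tile_width)  # ceil
    offsets = np.concatenate([[0], np.cumsum(n_tiles_per_chrom)])

    # both Tn5 insertion ends: start and end - 1 (still inside the fragment)
    pos = np.concatenate([fragments["start"].to_numpy(), fragments["end"].to_numpy() - 1])
    frag_chrom = np.concatenate([chrom_idx, chrom_idx])
    frag_cell = np.concatenate([cell_pos, cell_pos])
    if (pos < 0).any() or (pos >= lengths[frag_chrom]).any():
        raise ValueError("insertion position beyond chromosome length")

    global_tile = offsets[frag_chrom] + pos // tile_width
    counts = sp.coo_matrix(
        (np.ones(len(global_tile)), (global_tile, frag_cell)),
        shape=(int(offsets[-1]), len(cells)),
    ).tocsr()
    nonzero = np.flatnonzero(np.asarray(counts.sum(axis=1)).ravel() > 0)
    counts = counts[nonzero]
    names = []
    for t in nonzero:
        c = int(np.searchsorted(offsets, t, side="right") - 1)
        names.append(tile_name(chroms[c], int(t - offsets[c]), tile_width))
    return CountMatrix(np.asarray(names, dtype=object), cells, counts)


def parse_interval_names(names: Sequence[str]) -> pd.DataFrame:
    """Parse 'chrom:start-end' feature names back into an interval frame."""
    rows = []
    for n in names:
        chrom, span = str(n).rsplit(":", 1)
        start, end = span.split("-")
        rows.append((chrom, int(start), int(end)))
    return pd.DataFrame(rows, columns=["chrom", "start", "end"])


# ---------------------------------------------------------------------------
# iterative overlap peak merging

def _greedy_nonoverlap(peaks: pd.DataFrame) -> pd.DataFrame:
    """Score-ranked greedy overlap removal on one pool of scored intervals.

    Sort by score descending (ties broken by coordinate for determinism);
    accept the best peak, discard all candidates overlapping an accepted peak,
    repeat until exhausted.
    """
    if not len(peaks):
        return peaks
    pool = peaks.sort_values(
        ["score", "chrom", "start"], ascending=[False, True, True]
    ).reset_index(drop=True)
    accepted_rows = []
    accepted_by_chrom: dict[str, list[tuple[int, int]]] = {}
    for row in pool.itertuples(index=False):
        spans = accepted_by_chrom.get(row.chrom, [])
        if any(row.start < e and s < row.end for s, e in spans):
            continue
        accepted_rows.append(row)
        accepted_by_chrom.setdefault(row.chrom, []).append((row.start, row.end))
    out = pd.DataFrame(accepted_rows, columns=pool.columns)
    return out.sort_values(["chrom", "start"]).reset_index(drop=True)


def iterative_overlap_merge(
    candidates: Mapping[str, Mapping[str, pd.DataFrame]] | pd.DataFrame,
) -> pd.DataFrame:
    """Build a fixed-width, non-overlapping peak set by iterative overlap merging.

    ``candidates`` maps cluster -> replicate -> scored fixed-width intervals.
    Replicate pools are merged within each cluster first, then the per-cluster
    sets are pooled and merged across the dataset. A flat frame is treated as a
    single level. Mixed widths raise.
    """
    if isinstance(candidates, pd.DataFrame):
        pools = [validate_intervals(candidates, "candidate peak")]
    else:
        pools = []
        for cluster, reps in candidates.items():
            pooled = pd.concat(list(reps.values()), ignore_index=True)
            validate_intervals(pooled, "candidate peak")
            merged = _greedy_nonoverlap(pooled)
            merged = merged.assign(provenance=str(cluster))
            pools.append(merged)
    allpeaks = pd.concat(pools, ignore_index=True)
    if not len(allpeaks):
        return allpeaks
    widths = (allpeaks["end"] - allpeaks["start"]).unique()
    if len(widths) != 1:
        raise ValueError(f"candidate peaks have mixed widths: {sorted(widths)}")
    final = _greedy_nonoverlap(allpeaks)
    final = final.reset_index(drop=True)
    final["name"] = [
        f"{c}:{s}-{e}" for c, s, e in zip(final["chrom"], final["start"], final["end"])
    ]
    logger.info("[peaks] merged %d candidates into %d peaks", len(allpeaks), len(final))
    return final


# ---------------------------------------------------------------------------
# counting fragments in peaks

def count_fragments_in_peaks(
    fragments: pd.DataFrame,
    peaks: pd.DataFrame,
    cell_ids: Sequence[str] | None = None,
) -> CountMatrix:
    """Count Tn5 insertion ends falling inside each (non-overlapping) peak."""
    peaks = validate_intervals(peaks, "peak").reset_index(drop=True)
    cells = (
        np.asarray(list(cell_ids), dtype=object)
        if cell_ids is not None
        else pd.unique(fragments["cell"].to_numpy())
    )
    cell_pos = pd.Index(cells).get_indexer(fragments["cell"])
    pos = np.concatenate([fragments["start"].to_numpy(), fragments["end"].to_numpy() - 1])
    chrom = np.concatenate([fragments["chrom"].to_numpy()] * 2)
    frag_cell = np.concatenate([cell_pos, cell_pos])

    peak_rows = np.full(len(pos), -1, dtype=np.int64)
    for c, sub in peaks.groupby("chrom", sort=False):
        sub = sub.sort_values("start")
        starts = sub["start"].to_numpy()
        ends = sub["end"].to_numpy()
        orig = sub.index.to_numpy()
        m = chrom == c
        if not m.any():
            continue
        j = np.searchsorted(starts, pos[m], side="right") - 1
        ok = (j >= 0) & (pos[m] < ends[np.clip(j, 0, None)])
        rows = np.full(m.sum(), -1, dtype=np.int64)
        rows[ok] = orig[j[ok]]
        peak_rows[m] = rows
    inside = peak_rows >= 0
    names = peaks["name"].to_numpy(dtype=object) if "name" in peaks.columns else np.array(
        [f"{c}:{s}-{e}" for c, s, e in zip(peaks["chrom"], peaks["start"], peaks["end"])],
        dtype=object,
    )
    counts = sp.coo_matrix(
        (np.ones(int(inside.sum())), (peak_rows[inside], frag_cell[inside])),
        shape=(len(peaks), len(cells)),
    ).tocsr()
    return CountMatrix(names, cells, counts)


# ---------------------------------------------------------------------------
# gene activity scores

def distance_weight(d: np.ndarray | float, decay: float = 5_000.0) -> np.ndarray:
    """Distance weight exp(-|d|/decay) + exp(-1), d in bp from tile center to TSS."""
    return np.exp(-np.abs(d) / decay) + np.exp(-1.0)


def gene_length_factor(gene_length: np.ndarray) -> np.ndarray:
    """Map 1/gene_length linearly onto [1, 5] (shortest gene -> 5, longest -> 1)."""
    inv = 1.0 / np.asarray(gene_length, dtype=float)
    lo, hi = inv.min(), inv.max()
    if hi == lo:
        return np.ones_like(inv)
    return 1.0 + 4.0 * (inv - lo) / (hi - lo)


def gene_activity_scores(
    tiles: CountMatrix,
    genes: pd.DataFrame,
    cfg: AnalysisConfig | None = None,
) -> FeatureMatrix:
    """Distance-weighted chromatin-derived activity score per gene and cell.

    raw(g, c) = L(g) * sum over tiles with |center - TSS| <= gene_window of
    w(d) * tilecount(t, c); columns are then scaled to total 10,000 and
    log2(1 + x)-transformed. Genes with no tile in the window score 0.
    """
    cfg = cfg or AnalysisConfig()
    genes = genes.reset_index(drop=True)
    tile_frame = parse_interval_names(tiles.feature_ids)
    tile_frame["center"] = (tile_frame["start"] + tile_frame["end"]) / 2.0

    L = gene_length_factor(genes["gene_length"].to_numpy())
    rows, cols, data = [], [], []
    for c, sub in tile_frame.groupby("chrom", sort=False):
        centers = sub["center"].to_numpy()
        order = np.argsort(centers)
        centers_sorted = centers[order]
        tile_idx_sorted = sub.index.to_numpy()[order]
        gmask = genes["chrom"].to_numpy() == c
        for gi in np.flatnonzero(gmask):
            tss = float(genes["tss"].iloc[gi])
            lo = np.searchsorted(centers_sorted, tss - cfg.gene_window, side="left")
            hi = np.searchsorted(centers_sorted, tss + cfg.gene_window, side="right")
            if hi <= lo:
                continue
            d = centers_sorted[lo:hi] - tss
            w = distance_weight(d, cfg.decay) * L[gi]
            rows.extend([gi] * (hi - lo))
            cols.extend(tile_idx_sorted[lo:hi].tolist())
            data.extend(w.tolist())
    W = sp.coo_matrix(
        (data, (rows, cols)), shape=(len(genes), tiles.shape[0])
    ).tocsr()
    raw = W @ tiles.values.astype(float)

    totals = np.asarray(raw.sum(axis=0)).ravel()
    if (totals == 0).any():
        bad = tiles.cell_ids[np.flatnonzero(totals == 0)[0]]
        raise ValueError(f"all-zero cell in gene activity scores: {bad!r}")
    scaled = raw.multiply(10_000.0 / totals).tocsr()
    scaled.data = np.log2(1.0 + scaled.data)
    return FeatureMatrix(genes["gene_id"].to_numpy(dtype=object), tiles.cell_ids, scaled)
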