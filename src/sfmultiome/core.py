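"""Shared domain types for the multiome pipeline.

Coordinates are 0-based half-open (BED convention) everywhere: an interval
``[start, end)`` covers ``end - start`` base pairs and two intervals overlap
iff they share at least one base.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp

logger = logging.getLogger("sfmultiome.core")

CONDITIONS = ("healthy", "disease_early", "disease_established")

#: canonical column order for interval frames (peaks, tiles, motif hits)
INTERVAL_COLUMNS = ["chrom", "start", "end", "name", "score"]

#: canonical column order for gene-model frames
GENE_COLUMNS = ["gene_id", "chrom", "strand", "tss", "gene_length"]

#: required cell-metadata columns
METADATA_COLUMNS = [
    "cell_id",
    "sample_id",
    "condition",
    "cluster_label",
    "latent_time",
    "n_features_detected",
    "pct_mito",
]


@dataclass(frozen=True)
class GenomicInterval:
    """A 0-based half-open genomic interval with an optional score."""

    chrom: str
    start: int
    end: int
    score: float | None = None
    name: str | None = None

    def __post_init__(self) -> None:
        if self.start < 0 or self.start >= self.end:
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "require 0 <= start < end"
            )

    @property
    def width(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


@dataclass(frozen=True)
class GeneModel:
    """Gene annotation: TSS anchor, strand, and gene length in bp."""

    gene_id: str
    chrom: str
    strand: str
    tss: int
    gene_length: int

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"{self.gene_id}: strand must be '+' or '-'")
        if self.tss < 0:
            raise ValueError(f"{self.gene_id}: tss must be >= 0")
        if self.gene_length <= 0:
            raise ValueError(f"{self.gene_id}: gene_length must be > 0")


def _check_unique(ids: np.ndarray, what: str) -> None:
    if len(ids) != len(set(ids)):
        dupes = pd.Index(ids)[pd.Index(ids).duplicated()].unique().tolist()
        raise ValueError(f"duplicate {what}: {dupes[:5]}")


@dataclass
class FeatureMatrix:
    """A features x cells matrix with aligned id vectors.

    ``values`` is kept sparse (CSR) and may be real-valued; :class:`CountMatrix`
    adds the nonnegative-integer contract for raw counts.
    """

    feature_ids: np.ndarray
    cell_ids: np.ndarray
    values: sp.csr_matrix

    def __post_init__(self) -> None:
        self.feature_ids = np.asarray(self.feature_ids, dtype=object)
        self.cell_ids = np.asarray(self.cell_ids, dtype=object)
        if not sp.issparse(self.values):
            self.values = sp.csr_matrix(np.asarray(self.values))
        self.values = self.values.tocsr()
        if self.values.shape != (len(self.feature_ids), len(self.cell_ids)):
            raise ValueError(
                f"matrix shape {self.values.shape} inconsistent with "
                f"{len(self.feature_ids)} features x {len(self.cell_ids)} cells"
            )
        _check_unique(self.feature_ids, "feature ids")
        _check_unique(self.cell_ids, "cell ids")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def dense(self) -> np.ndarray:
        return np.asarray(self.values.todense())

    def feature_index(self) -> pd.Index:
        return pd.Index(self.feature_ids)

    def cell_index(self) -> pd.Index:
        return pd.Index(self.cell_ids)

    def subset_cells(self, cell_ids: Sequence[str]) -> "FeatureMatrix":
        idx = self.cell_index().get_indexer(list(cell_ids))
        if (idx < 0).any():
            missing = [c for c, i in zip(cell_ids, idx) if i < 0]
            raise KeyError(f"cells absent from matrix: {missing[:5]}")
        return type(self)(self.feature_ids, np.asarray(list(cell_ids), dtype=object),
                          self.values[:, idx])

    def subset_features(self, feature_ids: Sequence[str]) -> "FeatureMatrix":
        idx = self.feature_index().get_indexer(list(feature_ids))
        if (idx < 0).any():
            missing = [f for f, i in zip(feature_ids, idx) if i < 0]
            raise KeyError(f"features absent from matrix: {missing[:5]}")
        return type(self)(np.asarray(list(feature_ids), dtype=object), self.cell_ids,
                          self.values[idx, :])


@dataclass
class CountMatrix(FeatureMatrix):
    """Nonnegative integer features x cells count matrix (sparse)."""

    def __post_init__(self) -> None:
        super().__post_init__()
        data = self.values.data
        if data.size and (data < 0).any():
            raise ValueError("counts must be nonnegative")
        if data.size and not np.allclose(data, np.round(data)):
            raise ValueError("counts must be integers")


def validate_intervals(frame: pd.DataFrame, what: str = "interval") -> pd.DataFrame:
    """Validate an interval frame (chrom/start/end[/name/score]) in place."""
    for col in ("chrom", "start", "end"):
        if col not in frame.columns:
            raise ValueError(f"{what} frame missing column {col!r}")
    bad = (frame["start"] < 0) | (frame["start"] >= frame["end"])
    if bad.any():
        row = frame[bad].iloc[0]
        raise ValueError(
            f"invalid {what} {row['chrom']}:{row['start']}-{row['end']}: "
            "require 0 <= start < end"
        )
    return frame


def validate_gene_models(genes: pd.DataFrame) -> pd.DataFrame:
    for col in GENE_COLUMNS:
        if col not in genes.columns:
            raise ValueError(f"gene model frame missing column {col!r}")
    _check_unique(genes["gene_id"].to_numpy(), "gene ids")
    if (genes["gene_length"] <= 0).any():
        raise ValueError("gene_length must be > 0 for all genes")
    if (genes["tss"] < 0).any():
        raise ValueError("tss must be >= 0 for all genes")
    if not genes["strand"].isin(["+", "-"]).all():
        raise ValueError("strand must be '+' or '-'")
    return genes


def validate_metadata(meta: pd.DataFrame) -> pd.DataFrame:
    for col in METADATA_COLUMNS:
        if col not in meta.columns:
            raise ValueError(f"metadata missing column {col!r}")
    _check_unique(meta["cell_id"].to_numpy(), "cell ids")
    bad_cond = set(meta["condition"]) - set(CONDITIONS)
    if bad_cond:
        raise ValueError(f"unknown condition labels: {sorted(bad_cond)}")
    lt = meta["latent_time"].dropna()
    if len(lt) and ((lt < 0) | (lt > 1)).any():
        raise ValueError("latent_time must lie in [0, 1]")
    pm = meta["pct_mito"]
    if ((pm < 0) | (pm > 100)).any():
        raise ValueError("pct_mito must lie in [0, 100]")
    return meta


def is_disease(conditions: Iterable[str] | pd.Series) -> np.ndarray:
    """Boolean mask: condition labels other than 'healthy'."""
    arr = np.asarray(list(conditions) if not isinstance(conditions, pd.Series)
                     else conditions.to_numpy(), dtype=object)
    return arr != "healthy"


@dataclass
class MultiomeDataset:
    """A paired expression/accessibility dataset plus annotation.

    ``fragments`` holds scATAC fragments (cell, chrom, start, end); the tile
    matrix is derived from it so that total Tn5 insertions are conserved.
    """

    expression: CountMatrix
    tiles: CountMatrix
    metadata: pd.DataFrame
    genes: pd.DataFrame
    motif_hits: pd.DataFrame
    fragments: pd.DataFrame | None = None
    candidate_peaks: dict | None = None
    tile_width: int = 500
    genome: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        validate_metadata(self.metadata)
        validate_gene_models(self.genes)
        validate_intervals(self.motif_hits, "motif hit")
        self._check_cells()

    def _check_cells(self) -> None:
        for name, mat in (("expression", self.expression), ("tiles", self.tiles)):
            missing = set(self.metadata["cell_id"]) - set(mat.cell_ids)
            if missing:
                raise ValueError(
                    f"cells in metadata but absent from {name} matrix: "
                    f"{sorted(missing)[:5]}"
                )
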