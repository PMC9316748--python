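"""File I/O for the pipeline's standard formats.

Matrices travel as MatrixMarket triplets with ``*.features.tsv`` /
``*.barcodes.tsv`` sidecars, intervals as BED (0-based half-open, optional
name/score columns), gene models and cell metadata as TSV. Parsing is strict:
malformed lines fail fast with the offending line number rather than being
dropped, so synthetic pipelines stay deterministic.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

from .core import (
    GENE_COLUMNS,
    INTERVAL_COLUMNS,
    METADATA_COLUMNS,
    CountMatrix,
    FeatureMatrix,
    MultiomeDataset,
    validate_gene_models,
    validate_intervals,
    validate_metadata,
)

logger = logging.getLogger("sfmultiome.io")


# ---------------------------------------------------------------------------
# count matrices (MTX + sidecars)

def write_count_matrix(mat: FeatureMatrix, prefix: str | Path) -> None:
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    scipy.io.mmwrite(str(prefix) + ".mtx", mat.values.tocoo())
    pd.Series(mat.feature_ids).to_csv(
        str(prefix) + ".features.tsv", sep="\t", index=False, header=False
    )
    pd.Series(mat.cell_ids).to_csv(
        str(prefix) + ".barcodes.tsv", sep="\t", index=False, header=False
    )


def read_count_matrix(prefix: str | Path, kind: type = CountMatrix) -> FeatureMatrix:
    prefix = str(prefix)
    values = sp.csr_matrix(scipy.io.mmread(prefix + ".mtx"))
    features = pd.read_csv(prefix + ".features.tsv", sep="\t", header=None)[0]
    barcodes = pd.read_csv(prefix + ".barcodes.tsv", sep="\t", header=None)[0]
    return kind(features.to_numpy(dtype=object), barcodes.to_numpy(dtype=object), values)


# ---------------------------------------------------------------------------
# BED intervals

def write_bed(frame: pd.DataFrame, path: str | Path) -> None:
    frame = frame.copy()
    for col in ("name", "score"):
        if col not in frame.columns:
            frame[col] = "." if col == "name" else 0.0
    frame[INTERVAL_COLUMNS].to_csv(path, sep="\t", index=False, header=False)


def read_bed(path: str | Path) -> pd.DataFrame:
    """Strict BED3+ parser; raises naming the line number on malformed input."""
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}: line {lineno}: expected >= 3 BED fields")
            chrom = parts[0]
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError as exc:
                raise ValueError(
                    f"{path}: line {lineno}: non-integer coordinates"
                ) from exc
            if start < 0 or start >= end:
                raise ValueError(
                    f"{path}: line {lineno}: invalid interval "
                    f"{chrom}:{start}-{end} (require 0 <= start < end)"
                )
            name = parts[3] if len(parts) > 3 else "."
            score = float(parts[4]) if len(parts) > 4 else 0.0
            rows.append((chrom, start, end, name, score))
    return pd.DataFrame(rows, columns=INTERVAL_COLUMNS)


# ---------------------------------------------------------------------------
# TSV tables

def write_gene_models(genes: pd.DataFrame, path: str | Path) -> None:
    validate_gene_models(genes)[GENE_COLUMNS].to_csv(path, sep="\t", index=False)


def read_gene_models(path: str | Path) -> pd.DataFrame:
    return validate_gene_models(pd.read_csv(path, sep="\t"))


def write_metadata(meta: pd.DataFrame, path: str | Path) -> None:
    validate_metadata(meta)[METADATA_COLUMNS].to_csv(path, sep="\t", index=False)


def read_metadata(path: str | Path) -> pd.DataFrame:
    return validate_metadata(pd.read_csv(path, sep="\t"))


# ---------------------------------------------------------------------------
# dataset directories

def write_dataset(ds: MultiomeDataset, outdir: str | Path) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_count_matrix(ds.expression, outdir / "expression")
    write_count_matrix(ds.tiles, outdir / "tiles")
    write_metadata(ds.metadata, outdir / "metadata.tsv")
    write_gene_models(ds.genes, outdir / "genes.tsv")
    write_bed(ds.motif_hits, outdir / "motif_hits.bed")
    if ds.fragments is not None:
        ds.fragments.to_csv(outdir / "fragments.tsv", sep="\t", index=False)
    if ds.genome:
        pd.Series(ds.genome).rename_axis("chrom").rename("length").to_csv(
            outdir / "genome.tsv", sep="\t"
        )
    if ds.candidate_peaks:
        rows = []
        for cluster, reps in ds.candidate_peaks.items():
            for rep, frame in reps.items():
                frame = frame.copy()
                frame["cluster"], frame["replicate"] = cluster, rep
                rows.append(frame)
        pd.concat(rows).to_csv(outdir / "candidate_peaks.tsv", sep="\t", index=False)
    logger.info("[io] wrote dataset to %s", outdir)


def load_dataset(outdir: str | Path) -> MultiomeDataset:
    """Load a dataset directory written by :func:`write_dataset`.

    All cross-references are checked (every metadata cell must exist in both
    matrices); any violation raises instead of silently subsetting.
    """
    outdir = Path(outdir)
    expression = read_count_matrix(outdir / "expression")
    tiles = read_count_matrix(outdir / "tiles")
    metadata = read_metadata(outdir / "metadata.tsv")
    genes = read_gene_models(outdir / "genes.tsv")
    motif_hits = read_bed(outdir / "motif_hits.bed")
    fragments = None
    if (outdir / "fragments.tsv").exists():
        fragments = pd.read_csv(outdir / "fragments.tsv", sep="\t")
    genome = {}
    if (outdir / "genome.tsv").exists():
        g = pd.read_csv(outdir / "genome.tsv", sep="\t")
        genome = dict(zip(g["chrom"], g["length"]))
    candidate_peaks = None
    if (outdir / "candidate_peaks.tsv").exists():
        flat = pd.read_csv(outdir / "candidate_peaks.tsv", sep="\t")
        candidate_peaks = {
            cluster: {
                rep: sub.drop(columns=["cluster", "replicate"]).reset_index(drop=True)
                for rep, sub in grp.groupby("replicate")
            }
            for cluster, grp in flat.groupby("cluster")
        }
    validate_intervals(motif_hits, "motif hit")
    return MultiomeDataset(
        expression=expression,
        tiles=tiles,
        metadata=metadata,
        genes=genes,
        motif_hits=motif_hits,
        fragments=fragments,
        candidate_peaks=candidate_peaks,
        genome=genome,
    )
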