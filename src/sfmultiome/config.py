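"""Analysis configuration: every threshold of the pipeline with its default.

Thresholds follow the study's published cutoffs (QC, marker, peak, motif, and
regulator rules); knobs the study leaves unstated (link window, background
sampling, AUC fraction, priming operationalization) carry documented defaults
and are validated the same way.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, fields
from pathlib import Path
from typing import Any, Mapping

import yaml

logger = logging.getLogger("sfmultiome.config")


@dataclass(frozen=True)
class AnalysisConfig:
    # scRNA QC and markers
    min_genes: int = 500          # minimum detected genes per cell
    max_pct_mito: float = 10.0    # maximum % mitochondrial reads per cell
    scale_factor: float = 10_000.0
    pct_min: float = 0.25         # detection-fraction filter for markers
    lfc_min: float = 0.25         # |avgLFC| filter for markers (natural log)
    up_p: float = 0.01            # upregulated-gene p cutoff (unadjusted)
    # differential peaks / motifs
    peak_lfc: float = 0.58        # log2 fold-change cutoff for marker peaks
    peak_p: float = 0.01          # p cutoff for marker peaks
    motif_p: float = 0.05         # adjusted-p cutoff for motif enrichment
    # positive TF regulators
    r2_min: float = 0.5
    reg_padj: float = 0.05
    # gene activity scores
    tile: int = 500               # tile width (bp)
    gene_window: int = 100_000    # max |tile center - TSS| contributing (bp)
    decay: float = 5_000.0        # exponential decay length (bp)
    # peak-to-gene links
    link_window: int = 250_000    # max |peak center - TSS| for a link (bp)
    link_r_min: float = 0.45
    link_fdr: float = 1e-4
    n_pseudo: int = 100           # pseudo-cell aggregates for correlations
    # motif deviations
    n_background: int = 50
    n_bins: int = 10
    # regulons
    auc_top_frac: float = 0.05
    top_k: int = 200              # co-expression candidates before motif pruning
    min_targets: int = 10
    # trajectory / priming
    driver_quantile: float = 0.85  # likelihood quantile (top 15%) for drivers
    inactive_pct: float = 0.05     # "transcriptionally inactive" detection cutoff
    promoter_halfwidth: int = 2_000
    # misc
    mito_prefix: str = "mt-"
    seed: int = 1


# Fields exempt from the strictly-positive rule.
_NON_THRESHOLD = {"seed", "mito_prefix"}


def validate_config(raw: Mapping[str, Any] | None = None) -> AnalysisConfig:
    """Build an :class:`AnalysisConfig` from a key-value mapping.

    Missing keys take defaults (each applied default is logged); unknown keys
    and non-positive thresholds raise ``ValueError``.
    """
    raw = dict(raw or {})
    known = {f.name for f in fields(AnalysisConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    cfg = AnalysisConfig(**raw)
    for f in fields(AnalysisConfig):
        value = getattr(cfg, f.name)
        if f.name == "seed":
            if not isinstance(value, (int,)) or isinstance(value, bool):
                raise ValueError("seed must be an integer")
            continue
        if f.name in _NON_THRESHOLD:
            continue
        if not isinstance(value, (int, float)) or isinstance(value, bool):
            raise ValueError(f"config key {f.name!r} must be numeric")
        if value <= 0:
            raise ValueError(f"config key {f.name!r} must be strictly positive")
        if f.name not in raw:
            logger.debug("[config] default applied: %s = %r", f.name, value)
    return cfg


def load_config(path: str | Path) -> AnalysisConfig:
    """Load and validate a YAML config file (missing keys take defaults)."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ValueError(f"{path}: config must be a mapping")
    return validate_config(raw)
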