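"""Synthetic paired expression/accessibility generator with planted ground truth.

The generator emulates the statistical structure the downstream analysis
assumes: negative-binomial UMI counts with cluster structure across a healthy
and a disease condition, disease expansion of designated clusters, a lineage
with per-cell latent time rooted in one cluster, TF regulons whose targets and
motif-bearing enhancer peaks co-activate, trajectory-driven genes turning on
along latent time, and "primed" genes that are silent in the root state while
their promoters are already accessible there. Tn5 fragments are sampled
explicitly so tile counts conserve total insertions.

Every random draw flows from a single seed; the same design and seed yield
bit-identical output.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy import stats

from .atac import count_tiles
from .core import CountMatrix, MultiomeDataset, is_disease

logger = logging.getLogger("sfmultiome.simulate")


def _default_genome() -> dict[str, int]:
    # 10 x 30 Mb: with 2,000 genes this gives ~150-kb gene spacing, matching
    # the gene density of a mammalian genome so that the 100-kb gene-score
    # windows see a realistic number of neighboring regulatory elements
    return {f"chr{i}": 30_000_000 for i in range(1, 11)}


@dataclass(frozen=True)
class SimulationDesign:
    """Study conditions for the synthetic multiome.

    The default design plants 6 clusters x 200 cells/cluster/condition over a
    healthy and an established-disease condition (2,400 cells), 2,000 genes,
    5 TFs in 3 regulatory programs, and 4,000 fixed-width peaks on a 100-Mb
    genome.
    """

    n_clusters: int = 6
    cells_per_cluster_per_condition: int = 200
    n_genes: int = 2000
    n_tfs: int = 5
    n_peaks: int = 4000
    conditions: tuple[str, ...] = ("healthy", "disease_established")
    genome: Mapping[str, int] = field(default_factory=_default_genome)
    # cluster structure / lineage
    markers_per_cluster: int = 30
    marker_effect: float = 1.4           # ln-fold elevation in the home cluster
    expanding_factor: float = 2.0        # disease oversampling of expanding clusters
    # regulons
    tf_programs: tuple[int, ...] = (0, 0, 1, 1, 2)
    disease_programs: tuple[int, ...] = (2,)
    targets_per_tf: int = 40
    regulon_effect: float = 1.6          # ln-fold target activation when on
    tf_effect: float = 1.6               # ln-fold TF elevation when on
    disease_boost: float = 0.8           # extra ln-fold in disease cells
    # trajectory & priming
    n_trajectory_genes: int = 60
    n_primed: int = 40
    traj_alpha_low: float = 0.01         # off-state relative expression
    traj_alpha_high: float = 2.0         # on-state relative expression
    sigmoid_scale: float = 0.05          # latent-time activation sharpness
    # motifs
    n_decoy_motifs: int = 20
    motif_bg_hits: int = 10              # random background hits per motif
    motif_width: int = 15
    prior_extra_genes: int = 50          # non-target genes in each motif prior
    # accessibility
    peak_width: int = 500
    tile_width: int = 500
    open_low: float = 0.3                # closed promoter/enhancer openness
    open_coupling: float = 1.2           # ln-fold opening when the gene is active
    open_background: float = 1.5         # intergenic background peak openness
    open_primed: float = 4.0             # primed-gene promoter openness (all states)
    openness_jitter: float = 0.35        # per gene x cluster ln-openness noise
    atac_disease_boost: float = 0.6      # extra ln-opening in disease cells (disease programs)
    mean_fragments: float = 1500.0       # expected in-peak fragments per cell
    background_fragments: float = 300.0  # expected off-peak fragments per cell
    capture: float = 0.7                 # per-insertion capture probability
    candidate_min_count: int = 5         # pseudo-bulk count to call a candidate peak
    candidate_jitter: int = 50           # candidate peak center jitter (bp)
    # noise
    dispersion: float = 10.0             # NB size parameter (var = mu + mu^2/size)
    mean_depth: float = 5000.0           # expression counts per cell
    depth_sigma: float = 0.3             # per-cell lognormal depth spread
    seed: int = 1

    @property
    def cluster_names(self) -> list[str]:
        return [f"C{i}" for i in range(self.n_clusters)]

    @property
    def lineage_order(self) -> list[str]:
        return self.cluster_names

    @property
    def root_cluster(self) -> str:
        return self.lineage_order[0]

    @property
    def program_clusters(self) -> dict[int, tuple[str, ...]]:
        names = self.cluster_names
        programs = sorted(set(self.tf_programs))
        per = max(1, self.n_clusters // len(programs))
        out = {}
        for i, p in enumerate(programs):
            lo = i * per
            hi = self.n_clusters if i == len(programs) - 1 else (i + 1) * per
            out[p] = tuple(names[lo:hi])
        return out

    @property
    def expanding_clusters(self) -> tuple[str, ...]:
        out: list[str] = []
        for p in self.disease_programs:
            out.extend(self.program_clusters[p])
        return tuple(out)

    def validate(self) -> None:
        if self.lineage_order[0] != self.root_cluster:
            raise ValueError("lineage_order must start with the root cluster")
        positives = dict(
            n_clusters=self.n_clusters,
            cells_per_cluster_per_condition=self.cells_per_cluster_per_condition,
            n_genes=self.n_genes, n_tfs=self.n_tfs, n_peaks=self.n_peaks,
            targets_per_tf=self.targets_per_tf, peak_width=self.peak_width,
            tile_width=self.tile_width,
        )
        for k, v in positives.items():
            if v <= 0:
                raise ValueError(f"design field {k} must be positive")
        if len(self.tf_programs) != self.n_tfs:
            raise ValueError("tf_programs must assign one program per TF")
        if not set(self.disease_programs) <= set(self.tf_programs):
            raise ValueError("disease_programs must be a subset of tf_programs")
        if not (0 < self.capture <= 1):
            raise ValueError("capture must lie in (0, 1]")
        n_special = (self.n_tfs + self.n_clusters * self.markers_per_cluster
                     + self.n_tfs * self.targets_per_tf + self.n_trajectory_genes
                     + self.n_primed + self.n_decoy_motifs)
        if n_special > self.n_genes:
            raise ValueError("n_genes too small for the planted structure")
        n_planted_peaks = (self.n_genes + self.n_tfs * self.targets_per_tf
                           + self.n_primed)
        if n_planted_peaks > self.n_peaks:
            raise ValueError("n_peaks too small: need a promoter per gene plus "
                             "one enhancer per regulon target and primed gene")


@dataclass
class GroundTruth:
    """Planted structure for recovery metrics."""

    marker_genes: dict[str, list[str]]
    elevated: dict[str, set[str]]
    tf_ids: list[str]
    tf_program: dict[str, int]
    program_clusters: dict[int, tuple[str, ...]]
    regulon_targets: dict[str, list[str]]
    enhancer_peak: dict[str, str]       # target gene -> its enhancer peak name
    motif_prior: dict[str, set[str]]
    decoy_motifs: list[str]
    trajectory_genes: list[str]
    primed_genes: list[str]
    driver_genes: list[str]
    activation_time: dict[str, float]
    likelihood: pd.Series
    disease_tfs: list[str]
    disease_edges: set[tuple[str, str]]
    peaks: pd.DataFrame                 # true peak table with class/gene/tf
    promoter_log_openness: pd.DataFrame  # genes x clusters planted ln openness


@dataclass
class SimulatedMultiome:
    data: MultiomeDataset
    truth: GroundTruth
    design: SimulationDesign


# ---------------------------------------------------------------------------
# layout helpers

def _cell_layout(design: SimulationDesign, rng: np.random.Generator) -> pd.DataFrame:
    """Cluster/condition/latent-time assignment for every cell."""
    clusters = design.cluster_names
    rows = []
    per_condition_total = design.n_clusters * design.cells_per_cluster_per_condition
    expanding = set(design.expanding_clusters)
    for cond in design.conditions:
        if cond == "healthy":
            counts = {c: design.cells_per_cluster_per_condition for c in clusters}
        else:
            weights = np.array(
                [design.expanding_factor if c in expanding else 1.0 for c in clusters]
            )
            raw = weights / weights.sum() * per_condition_total
            counts = {c: int(round(r)) for c, r in zip(clusters, raw)}
            # preserve the per-condition total after rounding
            diff = per_condition_total - sum(counts.values())
            counts[clusters[-1]] += diff
        for c in clusters:
            rows.extend((c, cond) for _ in range(counts[c]))
    meta = pd.DataFrame(rows, columns=["cluster_label", "condition"])
    meta["cell_id"] = [f"cell{i:05d}" for i in range(len(meta))]
    rank = {c: i for i, c in enumerate(design.lineage_order)}
    jitter = rng.uniform(0, 1, len(meta))
    meta["latent_time"] = (
        meta["cluster_label"].map(rank).to_numpy() + jitter
    ) / design.n_clusters
    meta["sample_id"] = meta["condition"].astype(str) + "_s1"
    return meta[["cell_id", "sample_id", "condition", "cluster_label", "latent_time"]]


def _gene_roles(design: SimulationDesign) -> dict[str, list[str]]:
    ids = [f"g{i:04d}" for i in range(design.n_genes)]
    roles: dict[str, list[str]] = {}
    cursor = 0

    def take(n: int) -> list[str]:
        nonlocal cursor
        out = ids[cursor:cursor + n]
        cursor += n
        return out

    roles["tf"] = take(design.n_tfs)
    roles["marker"] = take(design.n_clusters * design.markers_per_cluster)
    roles["target"] = take(design.n_tfs * design.targets_per_tf)
    roles["trajectory"] = take(design.n_trajectory_genes)
    roles["primed"] = take(design.n_primed)
    roles["decoy_tf"] = take(design.n_decoy_motifs)
    roles["ordinary"] = ids[cursor:]
    roles["all"] = ids
    return roles


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def _relative_expression(
    design: SimulationDesign,
    meta: pd.DataFrame,
    roles: Mapping[str, list[str]],
    alpha: np.ndarray,
    t0: dict[str, float],
) -> np.ndarray:
    """Planted relative expression rel(g, c) for every gene and cell."""
    genes = roles["all"]
    gene_pos = {g: i for i, g in enumerate(genes)}
    n_cells = len(meta)
    cluster = meta["cluster_label"].to_numpy()
    disease = is_disease(meta["condition"])
    t = meta["latent_time"].to_numpy()

    rel = np.tile(alpha[:, None], (1, n_cells))

    # cluster markers
    clusters = design.cluster_names
    for ci, c in enumerate(clusters):
        block = roles["marker"][ci * design.markers_per_cluster:(ci + 1) * design.markers_per_cluster]
        idx = [gene_pos[g] for g in block]
        rel[np.ix_(idx, cluster == c)] *= np.exp(design.marker_effect)

    # TFs and regulon targets
    prog_clusters = design.program_clusters
    for ti, tf in enumerate(roles["tf"]):
        p = design.tf_programs[ti]
        on = np.isin(cluster, prog_clusters[p])
        rel[gene_pos[tf], on] *= np.exp(design.tf_effect)
        targets = roles["target"][ti * design.targets_per_tf:(ti + 1) * design.targets_per_tf]
        tidx = [gene_pos[g] for g in targets]
        rel[np.ix_(tidx, on)] *= np.exp(design.regulon_effect)
        if p in design.disease_programs:
            boost = on & disease
            rel[np.ix_(tidx, boost)] *= np.exp(design.disease_boost)

    # trajectory-driven and primed genes: sigmoid activation along latent time,
    # amplified in disease cells
    for g in roles["trajectory"] + roles["primed"]:
        gi = gene_pos[g]
        sig = _sigmoid((t - t0[g]) / design.sigmoid_scale)
        amp = np.where(disease, np.exp(design.disease_boost), 1.0)
        rel[gi] = design.traj_alpha_low + design.traj_alpha_high * sig * amp
    return rel


def expected_expression(design: SimulationDesign) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Noise-free expected expression (unit depth) and the cell layout.

    This is the dispersion -> infinity, capture = 1 limit of the generator:
    per-cell expected counts proportional to the planted relative expression.
    """
    design.validate()
    ss = np.random.SeedSequence(design.seed)
    rng_param = np.random.default_rng(ss.spawn(2)[0])
    meta = _cell_layout(design, rng_param)
    roles = _gene_roles(design)
    alpha, t0 = _draw_gene_params(design, roles, rng_param)
    rel = _relative_expression(design, meta, roles, alpha, t0)
    mu = rel * (design.mean_depth / rel.sum(axis=0).mean())
    return (
        pd.DataFrame(mu, index=roles["all"], columns=meta["cell_id"]),
        meta,
    )


def _draw_gene_params(
    design: SimulationDesign,
    roles: Mapping[str, list[str]],
    rng: np.random.Generator,
) -> tuple[np.ndarray, dict[str, float]]:
    genes = roles["all"]
    alpha = rng.lognormal(0.0, 0.5, len(genes))
    gene_pos = {g: i for i, g in enumerate(genes)}
    for g in roles["tf"]:
        alpha[gene_pos[g]] = 0.2
    # trajectory/primed genes take their own two-level form; baseline unused
    t0: dict[str, float] = {}
    n_traj = len(roles["trajectory"])
    for g, t in zip(roles["trajectory"], np.linspace(0.15, 0.85, max(n_traj, 1))):
        t0[g] = float(t)
    n_primed = len(roles["primed"])
    for g, t in zip(roles["primed"], np.linspace(0.55, 0.80, max(n_primed, 1))):
        t0[g] = float(t)
    return alpha, t0


# ---------------------------------------------------------------------------
# genome / peaks / motifs

def _place_genes_and_peaks(
    design: SimulationDesign,
    roles: Mapping[str, list[str]],
    rng: np.random.Generator,
) -> tuple[pd.DataFrame, pd.DataFrame, dict[str, str]]:
    """Gene models, true peak table, and target-gene -> enhancer-peak map."""
    genes = roles["all"]
    chroms = list(design.genome)
    per_chrom = int(np.ceil(len(genes) / len(chroms)))
    gene_rows = []
    for i, g in enumerate(genes):
        c = chroms[i // per_chrom]
        j = i % per_chrom
        spacing = (design.genome[c] - 100_000) // per_chrom
        tss = 60_000 + j * spacing + int(rng.integers(-2_000, 2_000))
        strand = "+" if rng.random() < 0.5 else "-"
        length = int(np.clip(rng.lognormal(np.log(20_000), 0.5), 1_000, 200_000))
        gene_rows.append((g, c, strand, tss, length))
    gene_models = pd.DataFrame(gene_rows, columns=["gene_id", "chrom", "strand", "tss",
                                                   "gene_length"])
    tss_lookup = gene_models.set_index("gene_id")

    half = design.peak_width // 2
    peak_rows = []  # chrom, start, end, class, gene, tf
    for g in genes:
        row = tss_lookup.loc[g]
        start = max(0, int(row["tss"]) - half)
        peak_rows.append((row["chrom"], start, start + design.peak_width,
                          "promoter", g, ""))

    enhancer_peak: dict[str, str] = {}

    def add_enhancer(g: str, tf: str) -> None:
        row = tss_lookup.loc[g]
        offset = int(rng.integers(8_000, 22_000)) * (1 if rng.random() < 0.5 else -1)
        center = max(half, int(row["tss"]) + offset)
        peak_rows.append((row["chrom"], center - half, center + half,
                          "enhancer", g, tf))

    for ti, tf in enumerate(roles["tf"]):
        targets = roles["target"][ti * design.targets_per_tf:(ti + 1) * design.targets_per_tf]
        for g in targets:
            add_enhancer(g, tf)

    # primed genes carry a distal disease-TF-bound element linked to them,
    # mirroring disease regulators preferentially targeting primed genes
    disease_tf_ids = [tf for ti, tf in enumerate(roles["tf"])
                      if design.tf_programs[ti] in design.disease_programs]
    if disease_tf_ids:
        for i, g in enumerate(roles["primed"]):
            add_enhancer(g, disease_tf_ids[i % len(disease_tf_ids)])

    # intergenic background peaks: clear of planted peaks and of every
    # promoter window, so "background" really means promoter-distal
    n_background = design.n_peaks - len(peak_rows)
    tss_zone = 2_500 + half
    planted_centers = {
        c: np.sort(np.array([ (s + e) // 2 for cc, s, e, *_ in peak_rows if cc == c ]))
        for c in chroms
    }
    tss_by_chrom = {
        c: np.sort(gene_models.loc[gene_models["chrom"] == c, "tss"].to_numpy())
        for c in chroms
    }
    placed = 0
    bg_centers: dict[str, list[int]] = {c: [] for c in chroms}
    while placed < n_background:
        c = chroms[int(rng.integers(len(chroms)))]
        pos = int(rng.integers(half, design.genome[c] - half))
        existing = planted_centers[c]
        k = np.searchsorted(existing, pos)
        near = [existing[j] for j in (k - 1, k) if 0 <= j < len(existing)]
        near += [p for p in bg_centers[c] if abs(p - pos) < design.peak_width]
        if any(abs(pos - p) < design.peak_width for p in near):
            continue
        tss = tss_by_chrom[c]
        kt = np.searchsorted(tss, pos)
        if any(abs(pos - tss[j]) < tss_zone for j in (kt - 1, kt) if 0 <= j < len(tss)):
            continue
        bg_centers[c].append(pos)
        peak_rows.append((c, pos - half, pos + half, "background", "", ""))
        placed += 1

    peaks = pd.DataFrame(peak_rows, columns=["chrom", "start", "end", "peak_class",
                                             "gene", "tf"])
    peaks["name"] = [f"{c}:{s}-{e}" for c, s, e in
                     zip(peaks["chrom"], peaks["start"], peaks["end"])]
    for _, p in peaks[peaks["peak_class"] == "enhancer"].iterrows():
        enhancer_peak[p["gene"]] = p["name"]
    return gene_models, peaks, enhancer_peak


def _motif_hits(
    design: SimulationDesign,
    roles: Mapping[str, list[str]],
    peaks: pd.DataFrame,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Motif hit intervals: each TF motif in its target enhancers plus random
    background peaks; decoy motifs only in random peaks."""
    w = design.motif_width
    rows = []

    def hit_in_peak(peak_row, motif):
        center = (int(peak_row["start"]) + int(peak_row["end"])) // 2
        rows.append((peak_row["chrom"], center - w // 2, center - w // 2 + w,
                     motif, 0.0))

    n_peaks = len(peaks)
    for ti, tf in enumerate(roles["tf"]):
        own = peaks[(peaks["peak_class"] == "enhancer") & (peaks["tf"] == tf)]
        for _, p in own.iterrows():
            hit_in_peak(p, tf)
        for j in rng.choice(n_peaks, design.motif_bg_hits, replace=False):
            hit_in_peak(peaks.iloc[int(j)], tf)
    for d in roles["decoy_tf"]:
        n_hits = design.motif_bg_hits * 4
        for j in rng.choice(n_peaks, n_hits, replace=False):
            hit_in_peak(peaks.iloc[int(j)], d)
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "name", "score"])


def _peak_openness(
    design: SimulationDesign,
    meta: pd.DataFrame,
    roles: Mapping[str, list[str]],
    peaks: pd.DataFrame,
    rel: np.ndarray,
    rng: np.random.Generator,
) -> tuple[np.ndarray, pd.DataFrame]:
    """Per-peak per-cell openness rates plus the planted promoter ln-openness
    (genes x clusters) used by recovery diagnostics.

    Promoter and enhancer openness couples to the planted activation of their
    gene (ln-openness = base + coupling * activation + per-cluster jitter);
    primed-gene promoters are constitutively open; background peaks sit at an
    intermediate constant level, so the median peak is more accessible than a
    closed promoter but far below a primed one.
    """
    genes = roles["all"]
    gene_pos = {g: i for i, g in enumerate(genes)}
    clusters = design.cluster_names
    cluster_arr = meta["cluster_label"].to_numpy()
    disease = is_disease(meta["condition"])
    n_cells = len(meta)
    primed = set(roles["primed"])

    # per-gene activation in [0, 1]: ln rel scaled to the gene's own range
    log_rel = np.log(rel)
    lo = log_rel.min(axis=1, keepdims=True)
    hi = log_rel.max(axis=1, keepdims=True)
    span = np.where(hi - lo > 0, hi - lo, 1.0)
    act = (log_rel - lo) / span

    openness = np.empty((len(peaks), n_cells))
    promoter_log = np.zeros((len(genes), len(clusters)))
    cluster_masks = {c: cluster_arr == c for c in clusters}

    for pi, p in enumerate(peaks.itertuples(index=False)):
        if p.peak_class == "background":
            openness[pi] = design.open_background
            continue
        g = p.gene
        gi = gene_pos[g]
        if p.peak_class == "promoter" and g in primed:
            openness[pi] = design.open_primed
            if pi < len(genes):
                promoter_log[gi] = np.log(design.open_primed)
            continue
        jitter = rng.normal(0.0, design.openness_jitter, len(clusters))
        ln_open_cluster = {}
        for ci, c in enumerate(clusters):
            m = cluster_masks[c]
            a = act[gi, m].mean() if m.any() else 0.0
            ln_open_cluster[c] = (
                np.log(design.open_low) + design.open_coupling * a + jitter[ci]
            )
        row = np.empty(n_cells)
        for c in clusters:
            row[cluster_masks[c]] = np.exp(ln_open_cluster[c])
        if p.peak_class == "enhancer" and p.tf:
            ti = roles["tf"].index(p.tf)
            if design.tf_programs[ti] in design.disease_programs:
                on = np.isin(cluster_arr, design.program_clusters[design.tf_programs[ti]])
                row[on & disease] *= np.exp(design.atac_disease_boost)
        openness[pi] = row
        if p.peak_class == "promoter":
            promoter_log[gi] = [ln_open_cluster[c] for c in clusters]

    promoter_frame = pd.DataFrame(promoter_log, index=genes, columns=clusters)
    return openness, promoter_frame


# ---------------------------------------------------------------------------
# main entry points

def simulate_multiome(design: SimulationDesign | None = None) -> SimulatedMultiome:
    """Generate a complete paired dataset with planted ground truth."""
    design = design or SimulationDesign()
    design.validate()
    ss = np.random.SeedSequence(design.seed)
    seeds = ss.spawn(2)
    rng_param = np.random.default_rng(seeds[0])
    rng_noise = np.random.default_rng(seeds[1])

    meta = _cell_layout(design, rng_param)
    roles = _gene_roles(design)
    alpha, t0 = _draw_gene_params(design, roles, rng_param)
    rel = _relative_expression(design, meta, roles, alpha, t0)

    # --- expression counts: NB via gamma-Poisson
    depth = rng_noise.lognormal(0.0, design.depth_sigma, len(meta))
    scale = design.mean_depth / rel.sum(axis=0).mean()
    mu = rel * scale * depth[None, :]
    size = design.dispersion
    lam = rng_noise.gamma(size, mu / size)
    counts = rng_noise.poisson(lam)
    expression = CountMatrix(
        np.asarray(roles["all"], dtype=object),
        meta["cell_id"].to_numpy(dtype=object),
        sp.csr_matrix(counts),
    )

    # --- genome, peaks, motifs
    gene_models, peaks, enhancer_peak = _place_genes_and_peaks(design, roles, rng_param)
    motif_hits = _motif_hits(design, roles, peaks, rng_param)

    # --- accessibility
    openness, promoter_log = _peak_openness(design, meta, roles, peaks, rel, rng_param)
    frag_budget = rng_noise.lognormal(np.log(design.mean_fragments), design.depth_sigma,
                                      len(meta))
    open_total = openness.mean(axis=1).sum()
    lam_atac = openness * (frag_budget / open_total)[None, :] * design.capture
    peak_counts = rng_noise.poisson(lam_atac)
    fragments = _sample_fragments(design, peaks, peak_counts, meta, rng_noise)
    tiles = count_tiles(fragments, design.genome, design.tile_width,
                        cell_ids=meta["cell_id"].tolist())

    # --- candidate peak calls per cluster (two pseudo-bulk replicates)
    candidate_peaks = _candidate_peaks(design, peaks, peak_counts, meta, rng_noise)

    # --- metadata QC columns
    n_detected = np.asarray((expression.values > 0).sum(axis=0)).ravel()
    meta = meta.assign(n_features_detected=n_detected, pct_mito=0.0)

    truth = _build_truth(design, roles, meta, rel, t0, peaks, enhancer_peak,
                         promoter_log, rng_param)
    data = MultiomeDataset(
        expression=expression,
        tiles=tiles,
        metadata=meta,
        genes=gene_models,
        motif_hits=motif_hits,
        fragments=fragments,
        candidate_peaks=candidate_peaks,
        tile_width=design.tile_width,
        genome=dict(design.genome),
    )
    logger.info("[simulate] %d cells, %d genes, %d true peaks, %d fragments",
                len(meta), design.n_genes, len(peaks), len(fragments))
    return SimulatedMultiome(data=data, truth=truth, design=design)


def _sample_fragments(
    design: SimulationDesign,
    peaks: pd.DataFrame,
    peak_counts: np.ndarray,
    meta: pd.DataFrame,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Explicit Tn5 fragments: in-peak fragments per sampled count plus a
    uniform genomic background."""
    pk_idx, cell_idx = np.nonzero(peak_counts)
    reps = peak_counts[pk_idx, cell_idx]
    pk_rep = np.repeat(pk_idx, reps)
    cell_rep = np.repeat(cell_idx, reps)
    starts_bound = peaks["start"].to_numpy()[pk_rep]
    ends_bound = peaks["end"].to_numpy()[pk_rep]
    lengths = rng.integers(50, 151, len(pk_rep))
    max_start = np.maximum(starts_bound, ends_bound - lengths)
    starts = starts_bound + (rng.random(len(pk_rep))
                             * np.maximum(1, max_start - starts_bound)).astype(np.int64)
    frag = pd.DataFrame(
        {
            "cell": meta["cell_id"].to_numpy(dtype=object)[cell_rep],
            "chrom": peaks["chrom"].to_numpy(dtype=object)[pk_rep],
            "start": starts,
            "end": starts + lengths,
        }
    )

    # background fragments uniform over the genome
    n_bg = rng.poisson(design.background_fragments, len(meta))
    total_bg = int(n_bg.sum())
    chroms = list(design.genome)
    chrom_lengths = np.array([design.genome[c] for c in chroms], dtype=float)
    chrom_probs = chrom_lengths / chrom_lengths.sum()
    bg_chrom_idx = rng.choice(len(chroms), total_bg, p=chrom_probs)
    bg_len = rng.integers(50, 151, total_bg)
    bg_start = (rng.random(total_bg)
                * (chrom_lengths[bg_chrom_idx] - bg_len - 1)).astype(np.int64)
    bg = pd.DataFrame(
        {
            "cell": np.repeat(meta["cell_id"].to_numpy(dtype=object), n_bg),
            "chrom": np.asarray(chroms, dtype=object)[bg_chrom_idx],
            "start": bg_start,
            "end": bg_start + bg_len,
        }
    )
    return pd.concat([frag, bg], ignore_index=True)


def _candidate_peaks(
    design: SimulationDesign,
    peaks: pd.DataFrame,
    peak_counts: np.ndarray,
    meta: pd.DataFrame,
    rng: np.random.Generator,
) -> dict[str, dict[str, pd.DataFrame]]:
    """Scored fixed-width candidate peak calls per cluster, two pseudo-bulk
    replicates each (random halves of the cluster's cells)."""
    half = design.peak_width // 2
    out: dict[str, dict[str, pd.DataFrame]] = {}
    cluster_arr = meta["cluster_label"].to_numpy()
    for c in design.cluster_names:
        cells = np.flatnonzero(cluster_arr == c)
        perm = rng.permutation(cells)
        halves = np.array_split(perm, 2)
        reps = {}
        for ri, idx in enumerate(halves):
            totals = peak_counts[:, idx].sum(axis=1)
            called = np.flatnonzero(totals >= design.candidate_min_count)
            jitter = rng.integers(-design.candidate_jitter,
                                  design.candidate_jitter + 1, len(called))
            center = ((peaks["start"].to_numpy()[called]
                       + peaks["end"].to_numpy()[called]) // 2 + jitter)
            center = np.maximum(center, half)
            reps[f"rep{ri + 1}"] = pd.DataFrame(
                {
                    "chrom": peaks["chrom"].to_numpy(dtype=object)[called],
                    "start": center - half,
                    "end": center + half,
                    "name": ".",
                    "score": totals[called] / max(1, len(idx)),
                }
            )
        out[c] = reps
    return out


def _build_truth(
    design: SimulationDesign,
    roles: Mapping[str, list[str]],
    meta: pd.DataFrame,
    rel: np.ndarray,
    t0: dict[str, float],
    peaks: pd.DataFrame,
    enhancer_peak: dict[str, str],
    promoter_log: pd.DataFrame,
    rng: np.random.Generator,
) -> GroundTruth:
    genes = roles["all"]
    gene_pos = {g: i for i, g in enumerate(genes)}
    clusters = design.cluster_names
    cluster_arr = meta["cluster_label"].to_numpy()
    t = meta["latent_time"].to_numpy()

    marker_genes = {
        c: roles["marker"][ci * design.markers_per_cluster:(ci + 1) * design.markers_per_cluster]
        for ci, c in enumerate(clusters)
    }
    # every gene with a planted elevation in a cluster (markers, active
    # regulon targets and TFs, late-activating trajectory/primed genes)
    cluster_mean = np.column_stack(
        [rel[:, cluster_arr == c].mean(axis=1) for c in clusters]
    )
    overall = rel.mean(axis=1)
    planted = set(roles["marker"] + roles["target"] + roles["trajectory"]
                  + roles["primed"] + roles["tf"])
    elevated = {
        c: {
            g for g in planted
            if cluster_mean[gene_pos[g], ci] > 1.2 * overall[gene_pos[g]]
        }
        for ci, c in enumerate(clusters)
    }

    tf_program = {tf: design.tf_programs[ti] for ti, tf in enumerate(roles["tf"])}
    regulon_targets = {
        tf: roles["target"][ti * design.targets_per_tf:(ti + 1) * design.targets_per_tf]
        for ti, tf in enumerate(roles["tf"])
    }
    motif_prior = {}
    non_targets = [g for g in genes if g not in set(roles["target"])]
    for tf in roles["tf"]:
        extras = rng.choice(len(non_targets), design.prior_extra_genes, replace=False)
        motif_prior[tf] = set(regulon_targets[tf]) | {non_targets[i] for i in extras}

    disease_tfs = [tf for tf in roles["tf"]
                   if tf_program[tf] in design.disease_programs]
    # planted disease edges: every enhancer whose motif belongs to a disease
    # TF and whose gene is disease-activated (regulon targets + primed genes)
    enh = peaks[(peaks["peak_class"] == "enhancer") & peaks["tf"].isin(disease_tfs)]
    disease_edges = set(zip(enh["tf"], enh["gene"]))

    # driver likelihood: monotone latent-time association of the planted
    # profile, squashed through a sigmoid plus a little noise
    lik = np.empty(len(genes))
    for gi in range(len(genes)):
        v = rel[gi]
        if np.ptp(v) == 0:
            rho = 0.0
        else:
            rho = stats.spearmanr(t, v).statistic
        rng_range = cluster_mean[gi].max() - cluster_mean[gi].min()
        norm_range = rng_range / max(cluster_mean[gi].max(), 1e-12)
        lik[gi] = _sigmoid(6.0 * (rho * norm_range - 0.35))
    lik = np.clip(lik + rng.normal(0, 0.03, len(genes)), 0.0, 1.0)
    likelihood = pd.Series(lik, index=genes, name="likelihood")

    driver_genes = sorted(
        set(roles["trajectory"]) | set(roles["primed"])
        | {g for tf in disease_tfs for g in regulon_targets[tf]}
    )

    return GroundTruth(
        marker_genes=marker_genes,
        elevated=elevated,
        tf_ids=list(roles["tf"]),
        tf_program=tf_program,
        program_clusters=design.program_clusters,
        regulon_targets=regulon_targets,
        enhancer_peak=enhancer_peak,
        motif_prior=motif_prior,
        decoy_motifs=list(roles["decoy_tf"]),
        trajectory_genes=list(roles["trajectory"]),
        primed_genes=list(roles["primed"]),
        driver_genes=driver_genes,
        activation_time=dict(t0),
        likelihood=likelihood,
        disease_tfs=disease_tfs,
        disease_edges=disease_edges,
        peaks=peaks,
        promoter_log_openness=promoter_log,
    )


# ---------------------------------------------------------------------------
# corruption (negative controls)

def corrupt_dataset(
    sim: SimulatedMultiome,
    dropout: float = 0.0,
    shuffle_labels: float = 0.0,
    shuffle_latent: float = 0.0,
    shuffle_pairing: float = 0.0,
    seed: int = 1,
) -> SimulatedMultiome:
    """Degraded copy for robustness tests.

    ``dropout`` zeroes each matrix entry independently; ``shuffle_labels``
    permutes cluster labels among a random fraction of cells (1.0 destroys all
    cluster-feature association in expectation); ``shuffle_latent`` does the
    same for latent time; ``shuffle_pairing`` permutes which cell barcode each
    expression profile belongs to, breaking the cross-modality pairing that
    per-cell correlations (regulators, peak-to-gene links) rely on. Knobs
    outside [0, 1] raise.
    """
    for name, knob in (("dropout", dropout), ("shuffle_labels", shuffle_labels),
                       ("shuffle_latent", shuffle_latent),
                       ("shuffle_pairing", shuffle_pairing)):
        if not (0.0 <= knob <= 1.0):
            raise ValueError(f"{name} must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    data = sim.data

    def thin(mat: CountMatrix) -> CountMatrix:
        if dropout == 0:
            return mat
        X = mat.values.copy().tocsr()
        keep = rng.random(X.nnz) >= dropout
        X.data = X.data * keep
        X.eliminate_zeros()
        return CountMatrix(mat.feature_ids, mat.cell_ids, X)

    meta = data.metadata.copy()
    for col, frac in (("cluster_label", shuffle_labels), ("latent_time", shuffle_latent)):
        if frac > 0:
            n = len(meta)
            chosen = rng.choice(n, size=int(round(frac * n)), replace=False)
            values = meta[col].to_numpy().copy()
            values[chosen] = values[rng.permutation(chosen)]
            meta[col] = values

    expression = data.expression
    if shuffle_pairing > 0:
        n = len(expression.cell_ids)
        chosen = rng.choice(n, size=int(round(shuffle_pairing * n)), replace=False)
        order = np.arange(n)
        order[chosen] = rng.permutation(chosen)
        expression = CountMatrix(
            expression.feature_ids, expression.cell_ids, expression.values[:, order]
        )

    new_data = MultiomeDataset(
        expression=thin(expression),
        tiles=thin(data.tiles),
        metadata=meta,
        genes=data.genes,
        motif_hits=data.motif_hits,
        fragments=data.fragments,
        candidate_peaks=data.candidate_peaks,
        tile_width=data.tile_width,
        genome=data.genome,
    )
    return SimulatedMultiome(data=new_data, truth=sim.truth, design=sim.design)
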