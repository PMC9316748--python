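"""Tile counting, iterative overlap merging, and gene activity scores."""

import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

from sfmultiome.atac import (
    count_fragments_in_peaks,
    count_tiles,
    distance_weight,
    gene_activity_scores,
    gene_length_factor,
    iterative_overlap_merge,
)
from sfmultiome.config import AnalysisConfig
from sfmultiome.core import CountMatrix
from tests.conftest import make_peaks

GENOME = {"chr1": 100_000}


def frags(rows):
    return pd.DataFrame(rows, columns=["cell", "chrom", "start", "end"])


class TestCountTiles:
    def test_half_open_tile_boundaries(self):
        # insertions at 0 and 499 -> tile [0,500); insertion at 500 -> [500,1000)
        f = frags([("c1", "chr1", 0, 500), ("c1", "chr1", 500, 560)])
        tiles = count_tiles(f, GENOME, 500)
        frame = dict(zip(tiles.feature_ids, np.asarray(tiles.values.todense()).ravel()))
        assert frame["chr1:0-500"] == 2          # ends at 0 and 499
        assert frame["chr1:500-1000"] == 2       # ends at 500 and 559

    def test_three_fragments_inside_one_tile_count_six(self):
        f = frags([("c1", "chr1", 1000, 1100)] * 3)
        tiles = count_tiles(f, GENOME, 500)
        assert tiles.values.sum() == 6
        assert list(tiles.feature_ids) == ["chr1:1000-1500"]

    def test_insertion_beyond_chromosome_raises(self):
        with pytest.raises(ValueError, match="beyond chromosome"):
            count_tiles(frags([("c1", "chr1", 99_990, 100_100)]), GENOME, 500)

    def test_insertion_conservation(self, small_sim):
        # total simulated Tn5 insertions (2 per fragment) equals the tile sum
        assert small_sim.data.tiles.values.sum() == 2 * len(small_sim.data.fragments)


def greedy_fixed_point_violations(candidates: pd.DataFrame, kept: pd.DataFrame) -> list:
    """Oracle: the merged set is the unique score-greedy fixed point.

    Every kept peak must overlap no higher-scoring kept peak, and every
    discarded candidate must overlap some kept peak with a higher score.
    """
    def overlaps(a, b):
        return a["chrom"] == b["chrom"] and a["start"] < b["end"] and b["start"] < a["end"]

    problems = []
    kept_rows = kept.to_dict("records")
    for a in kept_rows:
        for b in kept_rows:
            if a is not b and overlaps(a, b) and b["score"] > a["score"]:
                problems.append(("kept-overlaps-better", a, b))
    kept_keys = {(r["chrom"], r["start"], r["end"]) for r in kept_rows}
    for _, c in candidates.iterrows():
        if (c["chrom"], c["start"], c["end"]) in kept_keys:
            continue
        if not any(overlaps(c, b) and b["score"] > c["score"] for b in kept_rows):
            problems.append(("discarded-without-reason", dict(c)))
    return problems


class TestIterativeOverlapMerge:
    def test_single_peak_identity(self):
        p = make_peaks([("chr1", 100, 600, 2.0)])
        out = iterative_overlap_merge(p)
        assert len(out) == 1
        assert out.iloc[0]["start"] == 100

    def test_disjoint_peaks_both_kept(self):
        p = make_peaks([("chr1", 0, 500, 1.0), ("chr1", 1000, 1500, 9.0)])
        assert len(iterative_overlap_merge(p)) == 2

    def test_three_mutually_overlapping_keep_best(self):
        p = make_peaks(
            [("chr1", 0, 500, 5.0), ("chr1", 200, 700, 3.0), ("chr1", 400, 900, 1.0)]
        )
        out = iterative_overlap_merge(p)
        assert len(out) == 1
        assert out.iloc[0]["score"] == 5.0

    def test_mixed_widths_rejected(self):
        p = make_peaks([("chr1", 0, 500, 1.0), ("chr1", 1000, 1400, 2.0)])
        with pytest.raises(ValueError, match="mixed widths"):
            iterative_overlap_merge(p)

    def test_merge_of_nonoverlapping_set_is_identity(self):
        p = make_peaks([("chr1", i * 1000, i * 1000 + 500, float(i)) for i in range(5)])
        out = iterative_overlap_merge(p)
        assert len(out) == len(p)

    def test_two_level_merge_pools_clusters(self):
        # replicate-level then cluster-level: overlapping candidates across
        # clusters resolve to the higher-scoring cluster's peak
        c1 = {"rep1": make_peaks([("chr1", 0, 500, 2.0)]),
              "rep2": make_peaks([("chr1", 40, 540, 1.0)])}
        c2 = {"rep1": make_peaks([("chr1", 100, 600, 7.0)])}
        out = iterative_overlap_merge({"A": c1, "B": c2})
        assert len(out) == 1
        assert out.iloc[0]["score"] == 7.0

    def test_greedy_fixed_point_on_random_inputs(self):
        rng = np.random.default_rng(0)
        for _ in range(40):
            n = int(rng.integers(2, 9))
            starts = rng.choice(np.arange(0, 40, 5), size=n, replace=False)
            scores = rng.permutation(n) + 1.0
            p = make_peaks([("chr1", int(s), int(s) + 12, float(sc))
                            for s, sc in zip(starts, scores)])
            out = iterative_overlap_merge(p)
            assert greedy_fixed_point_violations(p, out) == []


class TestGeneActivityWeights:
    def test_weight_closed_forms(self):
        assert distance_weight(0.0) == pytest.approx(1 + np.exp(-1))
        assert distance_weight(5000.0) == pytest.approx(2 * np.exp(-1))
        assert distance_weight(-5000.0) == pytest.approx(2 * np.exp(-1))

    def test_weight_monotone_nonincreasing(self):
        d = np.linspace(0, 100_000, 200)
        w = distance_weight(d)
        assert np.all(np.diff(w) <= 1e-15)
        assert np.all(w > np.exp(-1))
        assert w[0] == pytest.approx(1 + np.exp(-1))

    def test_gene_length_factor_endpoints(self):
        L = gene_length_factor(np.array([1_000, 10_000, 100_000]))
        assert L[0] == pytest.approx(5.0)   # shortest gene -> 5
        assert L[2] == pytest.approx(1.0)   # longest gene -> 1
        assert 1.0 < L[1] < 5.0


def _toy_tiles_and_genes():
    genes = pd.DataFrame(
        {
            "gene_id": ["near", "far"],
            "chrom": ["chr1", "chr1"],
            "strand": ["+", "+"],
            "tss": [50_000, 500_000],
            "gene_length": [10_000, 10_000],
        }
    )
    # tiles: one centered on the TSS of "near", one 100,001+ bp away from it
    names = ["chr1:49750-50250", "chr1:155000-155500"]
    counts = np.array([[4.0, 8.0], [2.0, 4.0]])
    tiles = CountMatrix(np.asarray(names, dtype=object),
                        np.array(["c1", "c2"], dtype=object), sp.csr_matrix(counts))
    return tiles, genes


class TestGeneActivityScores:
    def test_window_cutoff_and_zero_score(self):
        tiles, genes = _toy_tiles_and_genes()
        scores = gene_activity_scores(tiles, genes)
        X = scores.dense()
        # "far" has no tile within 100 kb -> score 0, not an error
        assert np.all(X[1] == 0)
        assert np.all(X[0] > 0)

    def test_tile_beyond_window_contributes_nothing(self):
        tiles, genes = _toy_tiles_and_genes()
        # second tile center (155250) is 105,250 bp from the near TSS: its
        # counts must not change the score -> zeroing it leaves scores equal
        X0 = np.asarray(tiles.values.todense())
        X0[1] = 0
        alt = CountMatrix(tiles.feature_ids, tiles.cell_ids, sp.csr_matrix(X0))
        s_all = gene_activity_scores(tiles, genes).dense()
        s_zero = gene_activity_scores(alt, genes).dense()
        np.testing.assert_allclose(s_all[0], s_zero[0])

    def test_depth_invariance_proportional_cells(self):
        tiles, genes = _toy_tiles_and_genes()
        s = gene_activity_scores(tiles, genes).dense()
        # columns of the toy matrix are proportional (c2 = 2 x c1)
        np.testing.assert_allclose(s[:, 0], s[:, 1])

    def test_all_zero_cell_raises(self):
        tiles, genes = _toy_tiles_and_genes()
        X = np.asarray(tiles.values.todense())
        X[:, 1] = 0
        dead = CountMatrix(tiles.feature_ids, tiles.cell_ids, sp.csr_matrix(X))
        with pytest.raises(ValueError, match="c2"):
            gene_activity_scores(dead, genes)


class TestCountFragmentsInPeaks:
    def test_both_ends_counted_half_open(self):
        peaks = make_peaks([("chr1", 1000, 1500, 1.0)])
        f = frags([
            ("c1", "chr1", 1100, 1200),   # both ends inside -> 2
            ("c1", "chr1", 900, 1000),    # ends at 900 and 999, outside -> 0
            ("c1", "chr1", 1499, 1600),   # start inside, end-1 outside -> 1
        ])
        out = count_fragments_in_peaks(f, peaks, cell_ids=["c1"])
        assert out.values.sum() == 3
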