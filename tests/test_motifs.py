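"""Motif annotation, deviations, enrichment, and positive regulators."""

import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp
from scipy.special import comb

from sfmultiome.config import AnalysisConfig
from sfmultiome.core import CountMatrix, FeatureMatrix
from sfmultiome.motifs import (
    annotate_motifs,
    motif_deviations,
    motif_enrichment,
    positive_regulators,
    sample_background_peaks,
)
from tests.conftest import make_peaks


def hits(rows):
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "name", "score"])


THREE_PEAKS = make_peaks(
    [("chr1", 0, 500, 1.0), ("chr1", 1000, 1500, 1.0), ("chr2", 0, 500, 1.0)]
)


class TestAnnotateMotifs:
    def test_exact_and_abutting_hits(self):
        h = hits([
            ("chr1", 0, 500, "mExact", 0.0),     # equals peak 0 -> 1
            ("chr1", 500, 520, "mAbut", 0.0),    # abuts peak 0, half-open -> 0
        ])
        ann = annotate_motifs(THREE_PEAKS, h)
        M = np.asarray(ann.matrix.todense())
        exact = M[list(ann.motif_ids).index("mExact")]
        abut = M[list(ann.motif_ids).index("mAbut")]
        assert exact.tolist() == [1, 0, 0]
        assert abut.tolist() == [0, 0, 0]

    def test_toy_overlap_table(self):
        # m1 hits peaks 0 and 2 (different chroms); m2 hits peak 1 only
        h = hits([
            ("chr1", 490, 510, "m1", 0.0),
            ("chr2", 100, 120, "m1", 0.0),
            ("chr1", 1499, 1520, "m2", 0.0),
        ])
        ann = annotate_motifs(THREE_PEAKS, h)
        M = np.asarray(ann.matrix.todense())
        table = {m: M[i].tolist() for i, m in enumerate(ann.motif_ids)}
        assert table == {"m1": [1, 0, 1], "m2": [0, 1, 0]}


def _peak_matrix(values):
    values = np.asarray(values, dtype=float)
    return CountMatrix(
        np.asarray([f"p{i}" for i in range(values.shape[0])], dtype=object),
        np.asarray([f"c{i}" for i in range(values.shape[1])], dtype=object),
        sp.csr_matrix(values),
    )


class TestBackgroundPeaks:
    def test_deterministic_under_seed(self):
        pk = _peak_matrix(np.random.default_rng(0).poisson(2, (50, 10)))
        a = sample_background_peaks(pk, 20, 5, seed=4)
        b = sample_background_peaks(pk, 20, 5, seed=4)
        np.testing.assert_array_equal(a, b)

    def test_identical_peaks_single_stratum(self):
        pk = _peak_matrix(np.ones((30, 5)))
        bg = sample_background_peaks(pk, 50, 10, seed=0)
        # uniform sampling over all peaks: every peak appears somewhere
        assert set(np.unique(bg)) <= set(range(30))
        assert len(np.unique(bg)) > 20

    def test_separated_strata_do_not_mix(self):
        low = np.ones((20, 8))
        high = np.full((20, 8), 100.0)
        pk = _peak_matrix(np.vstack([low, high]))
        bg = sample_background_peaks(pk, 30, 2, seed=0)
        assert bg[:20].max() < 20      # low stratum stays low
        assert bg[20:].min() >= 20     # high stratum stays high


class TestMotifDeviations:
    def test_saturating_motif_has_zero_raw_deviation(self):
        rng = np.random.default_rng(5)
        X = rng.poisson(3, (20, 15)) + 1
        pk = _peak_matrix(X)
        ann_hits = hits([("chr1", i * 1000, i * 1000 + 20, "all", 0.0)
                         for i in range(20)])
        peaks = make_peaks([("chr1", i * 1000, i * 1000 + 500, 1.0)
                            for i in range(20)])
        ann = annotate_motifs(peaks, ann_hits)
        pk = CountMatrix(ann.peak_names, pk.cell_ids, pk.values)
        bg = sample_background_peaks(pk, 10, 3, seed=0)
        dev = motif_deviations(pk, ann, bg)
        np.testing.assert_allclose(dev.raw, 0.0, atol=1e-12)

    def test_identical_cells_have_identical_deviations(self):
        col = np.array([[3.0], [1.0], [2.0]])
        X = np.tile(col, (1, 4))
        pk = _peak_matrix(X)
        peaks = make_peaks([("chr1", i * 1000, i * 1000 + 500, 1.0) for i in range(3)])
        ann = annotate_motifs(
            peaks, hits([("chr1", 100, 120, "m", 0.0)])
        )
        pk = CountMatrix(ann.peak_names, pk.cell_ids, pk.values)
        bg = sample_background_peaks(pk, 5, 2, seed=0)
        dev = motif_deviations(pk, ann, bg)
        assert np.allclose(dev.raw, dev.raw[:, :1])
        assert np.allclose(dev.z, dev.z[:, :1])

    def test_raw_deviation_matches_hand_computation(self):
        # 3 peaks x 2 cells, motif on peak 0 only
        X = np.array([[4.0, 2.0], [2.0, 2.0], [2.0, 4.0]])
        pk = _peak_matrix(X)
        peaks = make_peaks([("chr1", i * 1000, i * 1000 + 500, 1.0) for i in range(3)])
        ann = annotate_motifs(peaks, hits([("chr1", 100, 120, "m", 0.0)]))
        pk = CountMatrix(ann.peak_names, pk.cell_ids, pk.values)
        bg = np.zeros((3, 2), dtype=np.int64)  # degenerate backgrounds: peak 0
        dev = motif_deviations(pk, ann, bg)
        # expected(m, c) = (6/16) * cell_total; raw = obs/exp - 1
        exp_c0 = 6 / 16 * 8
        exp_c1 = 6 / 16 * 8
        np.testing.assert_allclose(
            dev.raw[0], [4 / exp_c0 - 1, 2 / exp_c1 - 1], rtol=1e-12
        )

    def test_zero_count_cell_rejected(self):
        X = np.array([[1.0, 0.0], [2.0, 0.0]])
        pk = _peak_matrix(X)
        peaks = make_peaks([("chr1", 0, 500, 1.0), ("chr1", 1000, 1500, 1.0)])
        ann = annotate_motifs(peaks, hits([("chr1", 10, 30, "m", 0.0)]))
        pk = CountMatrix(ann.peak_names, pk.cell_ids, pk.values)
        with pytest.raises(ValueError, match="zero peak counts"):
            motif_deviations(pk, ann, np.zeros((2, 2), dtype=np.int64))


class TestMotifEnrichment:
    def _annotation(self):
        peaks = make_peaks([("chr1", i * 1000, i * 1000 + 500, 1.0) for i in range(10)])
        h = hits([("chr1", i * 1000 + 100, i * 1000 + 120, "mA", 0.0)
                  for i in range(4)]
                 + [("chr1", i * 1000 + 200, i * 1000 + 220, "mB", 0.0)
                    for i in range(10)])
        return annotate_motifs(peaks, h)

    def test_perfect_marker_overlap_closed_form(self):
        ann = self._annotation()
        markers = list(ann.peak_names[:4])  # exactly the mA-bearing peaks
        out = motif_enrichment(markers, ann).set_index("motif_id")
        assert out.loc["mA", "p"] == pytest.approx(1.0 / comb(10, 4), rel=1e-9)
        assert out.loc["mA", "enriched"]

    def test_uninformative_motif_not_enriched(self):
        ann = self._annotation()
        out = motif_enrichment(list(ann.peak_names[:4]), ann).set_index("motif_id")
        # mB annotates every peak: enrichment is impossible
        assert out.loc["mB", "p"] == pytest.approx(1.0)

    def test_empty_marker_set_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            motif_enrichment([], self._annotation())


def _dev_and_expr(z_rows, expr_rows, ids):
    from sfmultiome.motifs import DeviationMatrix

    cells = np.asarray([f"c{i}" for i in range(len(z_rows[0]))], dtype=object)
    dev = DeviationMatrix(
        np.asarray(ids, dtype=object), cells,
        np.asarray(z_rows, dtype=float), np.asarray(z_rows, dtype=float), 10,
    )
    expr = FeatureMatrix(np.asarray(ids, dtype=object), cells,
                         sp.csr_matrix(np.asarray(expr_rows, dtype=float)))
    return dev, expr


class TestPositiveRegulators:
    def test_identity_expression_retained(self):
        z = np.linspace(-2, 2, 30)
        dev, expr = _dev_and_expr([z], [z - z.min() + 0.1], ["tfA"])
        out = positive_regulators(dev, expr, ["tfA"])
        assert out.iloc[0]["positive"]
        assert out.iloc[0]["pearson_r"] == pytest.approx(1.0)

    def test_negative_correlation_rejected(self):
        z = np.linspace(-2, 2, 30)
        noise = np.random.default_rng(0).normal(0, 0.2, 30)
        dev, expr = _dev_and_expr([z], [-z + noise + 5], ["tfA"])
        out = positive_regulators(dev, expr, ["tfA"])
        assert out.iloc[0]["r_squared"] > 0.5
        assert not out.iloc[0]["positive"]  # r < 0

    def test_shuffled_expression_rejected(self):
        rng = np.random.default_rng(1)
        z = np.linspace(-2, 2, 40)
        dev, expr = _dev_and_expr([z], [rng.permutation(z) + 3], ["tfA"])
        out = positive_regulators(dev, expr, ["tfA"])
        assert not out.iloc[0]["positive"]

    def test_constant_vector_skipped(self):
        z = np.linspace(-2, 2, 10)
        dev, expr = _dev_and_expr([z], [np.ones(10)], ["tfA"])
        out = positive_regulators(dev, expr, ["tfA"])
        assert len(out) == 0
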