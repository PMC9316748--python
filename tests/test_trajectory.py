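"""Driver selection, phase assignment, and the primed-gene caller."""

import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

from sfmultiome.config import validate_config
from sfmultiome.core import CountMatrix, FeatureMatrix
from sfmultiome.trajectory import (
    assign_phases,
    call_primed_genes,
    empirical_likelihood,
    primed_tf_regulation,
    select_driver_genes,
)
from tests.conftest import make_peaks


class TestSelectDriverGenes:
    def test_two_step_intersection(self):
        likelihood = pd.Series({"gA": 0.95, "gB": 0.0, "gC": 0.9, "gD": 0.2})
        out = select_driver_genes(
            ["gA", "gB", "gC", "gD"],
            {"C4": ["gA", "gB"], "C5": ["gC"]},
            likelihood,
            validate_config({"driver_quantile": 0.5}),
        )
        sel = set(out[out["selected"]]["gene_id"])
        assert sel == {"gA", "gC"}           # DE in pathogenic disease contrast
        assert "gB" not in sel               # likelihood 0
        assert "gD" not in out["gene_id"].tolist()  # not disease-specific

    def test_missing_likelihood_treated_as_zero(self):
        likelihood = pd.Series({"gA": 0.9})
        out = select_driver_genes(
            ["gA", "gB"], {"C4": ["gA", "gB"]}, likelihood,
            validate_config({"driver_quantile": 0.5}),
        )
        row = out.set_index("gene_id").loc["gB"]
        assert row["likelihood"] == 0.0
        assert not row["selected"]


def _step_expression(t0s, times, noise=0.0, seed=0):
    rng = np.random.default_rng(seed)
    X = np.vstack([(times > t0).astype(float) * 2 for t0 in t0s])
    X += rng.normal(0, noise, X.shape)
    ids = [f"g{i}" for i in range(len(t0s))]
    cells = [f"c{i}" for i in range(len(times))]
    return FeatureMatrix(np.asarray(ids, dtype=object),
                         np.asarray(cells, dtype=object), sp.csr_matrix(X))


class TestAssignPhases:
    def test_step_functions_ordered_early_to_late(self):
        rng = np.random.default_rng(1)
        times = rng.uniform(0, 1, 300)
        t0s = [0.1] * 3 + [0.5] * 3 + [0.9] * 3
        norm = _step_expression(t0s, times, noise=0.05)
        out = assign_phases(norm, list(norm.feature_ids), times, k=3)
        phase = out.set_index("gene_id")["phase"]
        assert all(phase[f"g{i}"] == "early" for i in range(3))
        assert all(phase[f"g{i}"] == "intermediate" for i in range(3, 6))
        assert all(phase[f"g{i}"] == "late" for i in range(6, 9))

    def test_duplicated_gene_same_phase(self):
        rng = np.random.default_rng(2)
        times = rng.uniform(0, 1, 200)
        norm = _step_expression([0.2, 0.5, 0.8], times, noise=0.05)
        X = np.vstack([norm.dense(), norm.dense()[1:2]])
        ids = list(norm.feature_ids) + ["g1_copy"]
        dup = FeatureMatrix(np.asarray(ids, dtype=object), norm.cell_ids,
                            sp.csr_matrix(X))
        out = assign_phases(dup, ids, times, k=3).set_index("gene_id")["phase"]
        assert out["g1"] == out["g1_copy"]

    def test_cell_order_permutation_invariant(self):
        rng = np.random.default_rng(3)
        times = rng.uniform(0, 1, 150)
        norm = _step_expression([0.2, 0.5, 0.8], times, noise=0.05)
        perm = rng.permutation(150)
        permuted = FeatureMatrix(norm.feature_ids,
                                 norm.cell_ids[perm],
                                 sp.csr_matrix(norm.dense()[:, perm]))
        a = assign_phases(norm, list(norm.feature_ids), times, k=3)
        b = assign_phases(permuted, list(norm.feature_ids), times[perm], k=3)
        pd.testing.assert_series_equal(
            a.set_index("gene_id")["phase"], b.set_index("gene_id")["phase"]
        )

    def test_fewer_genes_than_phases_rejected(self):
        times = np.linspace(0, 1, 50)
        norm = _step_expression([0.5, 0.6], times)
        with pytest.raises(ValueError, match="at least 3"):
            assign_phases(norm, list(norm.feature_ids), times, k=3)


def _priming_fixture():
    """Two clusters (root R, downstream D) x two conditions, 40 cells.

    Genes: gPrimed (silent in root, downstream marker, disease-up, open root
    promoter); gRootActive (40% detection in root); gClosed (silent in root
    but closed promoter).
    """
    n = 40
    cells = [f"c{i}" for i in range(n)]
    cluster = np.array(["R"] * 20 + ["D"] * 20)
    condition = np.array((["healthy"] * 10 + ["disease_established"] * 10) * 2)
    rng = np.random.default_rng(0)
    X = np.zeros((3, n))
    X[0, cluster == "D"] = 3.0                      # gPrimed on downstream
    root_idx = np.flatnonzero(cluster == "R")
    X[1, root_idx[:8]] = 2.0                        # gRootActive: 40% of root
    X[1, cluster == "D"] = 2.0
    # gClosed stays 0 everywhere
    norm = FeatureMatrix(np.array(["gPrimed", "gRootActive", "gClosed"], dtype=object),
                         np.asarray(cells, dtype=object), sp.csr_matrix(X))
    meta = pd.DataFrame(
        {"cell_id": cells, "cluster_label": cluster, "condition": condition}
    )
    genes = pd.DataFrame(
        {
            "gene_id": ["gPrimed", "gRootActive", "gClosed"],
            "chrom": ["chr1"] * 3,
            "strand": ["+"] * 3,
            "tss": [10_000, 50_000, 90_000],
            "gene_length": [10_000] * 3,
        }
    )
    peaks = make_peaks(
        [
            ("chr1", 9_750, 10_250, 1.0),    # gPrimed promoter
            ("chr1", 49_750, 50_250, 1.0),   # gRootActive promoter
            ("chr1", 89_750, 90_250, 1.0),   # gClosed promoter
            ("chr1", 200_000, 200_500, 1.0),  # background peaks set the median
            ("chr1", 300_000, 300_500, 1.0),
        ]
    )
    acc = np.ones((5, n))
    acc[0] = 8.0                                   # primed promoter open everywhere
    acc[1, cluster == "R"] = 8.0                   # root-active promoter open in root
    acc[2] = 0.1                                   # closed promoter
    acc[3] = acc[4] = 1.0
    pk = CountMatrix(peaks["name"].to_numpy(dtype=object),
                     np.asarray(cells, dtype=object),
                     sp.csr_matrix(np.round(acc * 4)))
    return norm, meta, genes, peaks, pk


class TestCallPrimedGenes:
    def test_four_criteria(self):
        norm, meta, genes, peaks, pk = _priming_fixture()
        out = call_primed_genes(
            norm, meta, "R", ["D"],
            {"D": ["gPrimed", "gRootActive"]},
            ["gPrimed", "gRootActive"],
            pk, peaks, genes,
        ).set_index("gene_id")
        assert out.loc["gPrimed", "primed"]
        assert not out.loc["gRootActive", "primed"]      # 40% root detection
        assert not out.loc["gRootActive", "root_inactive"]
        assert not out.loc["gClosed", "primed"]          # silent + closed
        assert not out.loc["gClosed", "later_activated"]
        assert not out.loc["gClosed", "promoter_open_in_root"]

    def test_missing_root_cluster_rejected(self):
        norm, meta, genes, peaks, pk = _priming_fixture()
        with pytest.raises(ValueError, match="root cluster"):
            call_primed_genes(norm, meta, "NOPE", ["D"], {}, [], pk, peaks, genes)

    def test_tightening_inactive_pct_shrinks_set(self):
        norm, meta, genes, peaks, pk = _priming_fixture()
        down = {"D": ["gPrimed", "gRootActive"]}
        up = ["gPrimed", "gRootActive"]
        loose = call_primed_genes(
            norm, meta, "R", ["D"], down, up, pk, peaks, genes,
            validate_config({"inactive_pct": 0.5}),
        )
        tight = call_primed_genes(
            norm, meta, "R", ["D"], down, up, pk, peaks, genes,
            validate_config({"inactive_pct": 0.01}),
        )
        loose_set = set(loose[loose["primed"]]["gene_id"])
        tight_set = set(tight[tight["primed"]]["gene_id"])
        assert tight_set <= loose_set


class TestPrimedTfRegulation:
    def test_matrix_matches_manual_lookup(self):
        grn = pd.DataFrame(
            {
                "tf_id": ["t1", "t1", "t2", "t3"],
                "peak": ["p1", "p2", "p3", "p4"],
                "gene_id": ["gA", "gB", "gA", "gZ"],
            }
        )
        primed = ["gA", "gB", "gC", "gD", "gE"]
        mat, summary = primed_tf_regulation(primed, grn, ["t1", "t2", "t3"])
        assert mat.loc["t1"].tolist() == [1, 1, 0, 0, 0]
        assert mat.loc["t2"].tolist() == [1, 0, 0, 0, 0]
        assert mat.loc["t3"].tolist() == [0, 0, 0, 0, 0]
        pct = summary.set_index("tf_id")["pct_regulated"]
        assert pct["t1"] == pytest.approx(40.0)
        assert pct["t3"] == pytest.approx(0.0)

    def test_empty_primed_set_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            primed_tf_regulation([], pd.DataFrame(columns=["tf_id", "peak", "gene_id"]),
                                 ["t1"])


class TestEmpiricalLikelihood:
    def test_monotone_gene_scores_high(self):
        rng = np.random.default_rng(4)
        times = rng.uniform(0, 1, 300)
        X = np.vstack([
            (times > 0.5) * 3.0 + rng.normal(0, 0.1, 300),   # monotone
            rng.normal(2, 0.5, 300),                         # flat
        ])
        norm = FeatureMatrix(np.array(["mono", "flat"], dtype=object),
                             np.asarray([f"c{i}" for i in range(300)], dtype=object),
                             sp.csr_matrix(X))
        lik = empirical_likelihood(norm, times)
        assert lik["mono"] > 0.8
        assert lik["flat"] < 0.3

    def test_shuffled_time_collapses_scores(self):
        rng = np.random.default_rng(5)
        times = rng.uniform(0, 1, 300)
        X = ((times > 0.5) * 3.0 + rng.normal(0, 0.1, 300))[None, :]
        norm = FeatureMatrix(np.array(["mono"], dtype=object),
                             np.asarray([f"c{i}" for i in range(300)], dtype=object),
                             sp.csr_matrix(X))
        lik_true = empirical_likelihood(norm, times)
        lik_shuf = empirical_likelihood(norm, rng.permutation(times))
        assert lik_true["mono"] > 0.8
        assert lik_shuf["mono"] < 0.3
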