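"""Regulon inference, AUC scoring, homolog mapping, and module clustering."""

import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp
from hypothesis import given, settings
from hypothesis import strategies as st

from sfmultiome.core import CountMatrix, FeatureMatrix
from sfmultiome.regulons import (
    Regulon,
    cluster_regulon_modules,
    conserved_regulons,
    infer_regulons,
    map_homologs,
    resolve_homologs,
    score_regulon_auc,
)


def _matrix(values, genes=None, cells=None):
    values = np.asarray(values, dtype=float)
    genes = genes or [f"g{i}" for i in range(values.shape[0])]
    cells = cells or [f"c{i}" for i in range(values.shape[1])]
    return FeatureMatrix(np.asarray(genes, dtype=object),
                         np.asarray(cells, dtype=object), sp.csr_matrix(values))


class TestHomologs:
    def test_ambiguous_pairs_dropped(self):
        table = pd.DataFrame(
            {"a": ["h1", "h2", "h2", "h3"], "b": ["m1", "m2", "m3", "m4"]}
        )
        out = resolve_homologs(table)
        assert set(out["a"]) == {"h1", "h3"}

    def test_identity_table_preserves_matrix(self):
        mat = _matrix(np.arange(6).reshape(3, 2), genes=["x", "y", "z"])
        table = pd.DataFrame({"a": ["x", "y", "z"], "b": ["x", "y", "z"]})
        out = map_homologs(mat, table)
        assert list(out.feature_ids) == ["x", "y", "z"]
        assert (out.values != mat.values).nnz == 0

    def test_rename_and_drop_unmapped(self):
        mat = _matrix(np.arange(10).reshape(5, 2),
                      genes=["h1", "h2", "h3", "h4", "h5"])
        table = pd.DataFrame({"a": ["h1", "h3", "h9"], "b": ["m1", "m3", "m9"]})
        out = map_homologs(mat, table)
        assert list(out.feature_ids) == ["m1", "m3"]
        np.testing.assert_array_equal(out.dense(), mat.dense()[[0, 2]])

    def test_empty_intersection_rejected(self):
        mat = _matrix(np.ones((2, 2)), genes=["x", "y"])
        table = pd.DataFrame({"a": ["q"], "b": ["m"]})
        with pytest.raises(ValueError, match="no genes"):
            map_homologs(mat, table)


class TestInferRegulons:
    def test_noiseless_regulon_recovered_exactly(self):
        rng = np.random.default_rng(0)
        tf = rng.normal(0, 1, 100)
        targets = np.vstack([tf * 2, tf + 1, -tf])     # exact functions of TF
        noise = rng.normal(0, 1, (6, 100))
        X = np.vstack([tf, targets, noise])
        genes = ["tf"] + [f"t{i}" for i in range(3)] + [f"n{i}" for i in range(6)]
        norm = _matrix(X, genes=genes)
        prior = {"tf": {"t0", "t1", "t2"}}
        regs = infer_regulons(norm, ["tf"], prior, top_k=5, min_targets=1)
        assert len(regs) == 1
        assert set(regs[0].targets) == {"t0", "t1", "t2"}

    def test_candidate_without_motif_evidence_pruned(self):
        rng = np.random.default_rng(1)
        tf = rng.normal(0, 1, 100)
        X = np.vstack([tf, tf * 3, rng.normal(0, 1, 100)])
        norm = _matrix(X, genes=["tf", "copilot", "noise"])
        regs = infer_regulons(norm, ["tf"], {"tf": set()}, top_k=2, min_targets=0)
        # perfect co-expression but no motif evidence -> empty, discarded
        assert regs == [] or regs[0].targets == []

    def test_constant_tf_skipped(self):
        norm = _matrix(np.vstack([np.ones(10), np.arange(10)]), genes=["tf", "g"])
        assert infer_regulons(norm, ["tf"], {"tf": {"g"}}, min_targets=1) == []

    def test_small_regulon_discarded(self):
        rng = np.random.default_rng(2)
        tf = rng.normal(0, 1, 50)
        norm = _matrix(np.vstack([tf, tf * 2]), genes=["tf", "t0"])
        regs = infer_regulons(norm, ["tf"], {"tf": {"t0"}}, min_targets=10)
        assert regs == []


class TestScoreRegulonAuc:
    def test_maximal_configuration_hits_one(self):
        # regulon genes occupy the very top ranks
        X = np.array([[9.0], [8.0], [1.0], [0.5], [0.2], [0.1], [0.0], [0.0],
                      [0.0], [0.0]])
        norm = _matrix(X)
        auc = score_regulon_auc(norm, ["g0", "g1"], top_frac=0.5)
        assert auc.iloc[0] == pytest.approx(1.0)

    def test_all_below_cutoff_hits_zero(self):
        X = np.vstack([np.full((5, 1), 9.0), np.zeros((5, 1))])
        norm = _matrix(X)
        auc = score_regulon_auc(norm, ["g7", "g8"], top_frac=0.2)
        assert auc.iloc[0] == 0.0

    def test_hand_trapezoid_value(self):
        # 10 genes, regulon at ranks 1 and 5, top_frac 0.5:
        # recovery y = [1,1,1,1,2]; trapezoid = 0.5 + 1 + 1 + 1 + 1.5 = 5
        # maximal y = [1,2,2,2,2]; trapezoid = 0.5 + 1.5 + 2 + 2 + 2 = 8
        X = np.array([[10.0], [7.0], [6.0], [5.0], [4.0], [3.0], [2.0], [1.0],
                      [0.5], [0.1]])
        norm = _matrix(X)
        auc = score_regulon_auc(norm, ["g0", "g4"], top_frac=0.5)
        assert auc.iloc[0] == pytest.approx(5.0 / 8.0)

    def test_bounds_on_random_data(self):
        rng = np.random.default_rng(3)
        norm = _matrix(rng.normal(0, 1, (50, 20)))
        auc = score_regulon_auc(norm, [f"g{i}" for i in range(0, 50, 7)],
                                top_frac=0.3)
        assert ((auc >= 0) & (auc <= 1)).all()

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=15, deadline=None, derandomize=True)
    def test_invariant_under_monotone_transform(self, seed):
        rng = np.random.default_rng(seed)
        X = rng.normal(0, 2, (30, 5))
        norm = _matrix(X)
        regulon = [f"g{i}" for i in rng.choice(30, 6, replace=False)]
        base = score_regulon_auc(norm, regulon, top_frac=0.4)
        warped = _matrix(np.exp(X / 3) + 5)
        np.testing.assert_allclose(
            base.to_numpy(),
            score_regulon_auc(warped, regulon, top_frac=0.4).to_numpy(),
        )

    def test_disjoint_regulon_rejected(self):
        norm = _matrix(np.ones((3, 2)))
        with pytest.raises(ValueError, match="disjoint"):
            score_regulon_auc(norm, ["absent"], top_frac=0.5)

    def test_top_frac_domain(self):
        norm = _matrix(np.ones((3, 2)))
        with pytest.raises(ValueError, match="top_frac"):
            score_regulon_auc(norm, ["g0"], top_frac=0.9)


class TestConservedRegulons:
    def test_identical_sets_jaccard_one(self):
        regs = [Regulon("t1", ["a", "b"]), Regulon("t2", ["c"])]
        out = conserved_regulons(regs, regs)
        assert list(out["tf_id"]) == ["t1", "t2"]
        assert (out["jaccard"] == 1.0).all()

    def test_disjoint_tfs_empty(self):
        out = conserved_regulons([Regulon("t1", ["a"])], [Regulon("t2", ["a"])])
        assert len(out) == 0

    def test_partial_overlap_with_homolog_mapping(self):
        a = [Regulon("t1", ["gA", "gB", "gC"])]
        b = [Regulon("m_t1", ["m_gB", "m_gC", "m_gD"])]
        table = pd.DataFrame(
            {"a": ["t1", "gA", "gB", "gC", "gD"],
             "b": ["m_t1", "m_gA", "m_gB", "m_gC", "m_gD"]}
        )
        out = conserved_regulons(a, b, table)
        assert list(out["tf_id"]) == ["t1"]
        assert out.iloc[0]["conserved_targets"] == ["gB", "gC"]
        assert out.iloc[0]["jaccard"] == pytest.approx(2 / 4)

    def test_symmetric_in_species(self):
        a = [Regulon("t1", ["gA", "gB"]), Regulon("t2", ["gC"])]
        b = [Regulon("t1", ["gB"]), Regulon("t3", ["gD"])]
        ab = conserved_regulons(a, b)
        ba = conserved_regulons(b, a)
        assert list(ab["tf_id"]) == list(ba["tf_id"])
        np.testing.assert_allclose(ab["jaccard"], ba["jaccard"])


class TestClusterRegulonModules:
    def _block_deviations(self, rng):
        base1 = rng.normal(0, 1, 40)
        base2 = rng.normal(0, 1, 40)
        rows = [base1 + rng.normal(0, 0.05, 40) for _ in range(3)]
        rows += [base2 + rng.normal(0, 0.05, 40) for _ in range(2)]
        return pd.DataFrame(
            rows, index=[f"tf{i}" for i in range(5)],
            columns=[f"c{i}" for i in range(40)],
        )

    def test_perfect_blocks_recovered(self):
        frame = self._block_deviations(np.random.default_rng(0))
        out = cluster_regulon_modules(frame, list(frame.index), k=2)
        mods = out.set_index("tf_id")["module"]
        assert len({mods["tf0"], mods["tf1"], mods["tf2"]}) == 1
        assert len({mods["tf3"], mods["tf4"]}) == 1
        assert mods["tf0"] != mods["tf3"]

    def test_duplicated_tf_same_module(self):
        frame = self._block_deviations(np.random.default_rng(1))
        frame.loc["tf0_copy"] = frame.loc["tf0"]
        out = cluster_regulon_modules(frame, list(frame.index), k=2)
        mods = out.set_index("tf_id")["module"]
        assert mods["tf0"] == mods["tf0_copy"]

    def test_input_order_invariant(self):
        frame = self._block_deviations(np.random.default_rng(2))
        a = cluster_regulon_modules(frame, list(frame.index), k=2)
        shuffled = ["tf3", "tf0", "tf4", "tf1", "tf2"]
        b = cluster_regulon_modules(frame, shuffled, k=2)
        a_map = a.set_index("tf_id")["module"]
        b_map = b.set_index("tf_id")["module"]
        # same partition up to relabeling
        for x in frame.index:
            for y in frame.index:
                assert (a_map[x] == a_map[y]) == (b_map[x] == b_map[y])

    def test_k_exceeding_tfs_rejected(self):
        frame = self._block_deviations(np.random.default_rng(3))
        with pytest.raises(ValueError, match="exceeds"):
            cluster_regulon_modules(frame, list(frame.index), k=9)

    def test_context_labels_by_highest_mean_deviation(self):
        frame = pd.DataFrame(
            [[3.0, 3.0, 0.0, 0.0], [0.0, 0.0, 3.0, 3.0]],
            index=["tfA", "tfB"], columns=["c0", "c1", "c2", "c3"],
        )
        context = pd.Series(["lining", "lining", "sublining", "sublining"],
                            index=["c0", "c1", "c2", "c3"])
        out = cluster_regulon_modules(frame, ["tfA", "tfB"], k=2, context=context)
        labels = out.set_index("tf_id")["label"]
        assert labels["tfA"] == "lining"
        assert labels["tfB"] == "sublining"
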