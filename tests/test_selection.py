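"""Tests for mutual information, SAMI, fusion and OFS."""

import math

import numpy as np
import pandas as pd
import pytest

from dermfeat import selection, synth
from dermfeat.classify import MLPConfig
from dermfeat.selection import (AttentionProjections, MIEstimator,
                                mutual_information,
                                mutual_information_from_joint)
from dermfeat.synth import TableSpec

FAST_MLP = MLPConfig(max_epochs=8, patience=4, seed=0)


class TestMutualInformation:
    def test_identity_binary(self):
        rng = np.random.default_rng(0)
        x = rng.integers(0, 2, 2000).astype(float)
        mi = mutual_information(x, x)
        assert mi == pytest.approx(math.log(2), abs=0.01)

    def test_independent_coins(self):
        rng = np.random.default_rng(1)
        x = rng.integers(0, 2, 10000).astype(float)
        y = rng.integers(0, 2, 10000).astype(float)
        assert mutual_information(x, y) <= 0.01

    def test_joint_table_reference_value(self):
        P = np.array([[0.4, 0.1], [0.1, 0.4]])
        assert mutual_information_from_joint(P) == pytest.approx(0.1927,
                                                                 abs=5e-5)

    def test_joint_closed_form_oracle(self):
        rng = np.random.default_rng(2)
        for _ in range(50):
            P = rng.random((2, 2))
            P /= P.sum()
            px, py = P.sum(axis=1), P.sum(axis=0)
            oracle = sum(
                P[i, j] * math.log(P[i, j] / (px[i] * py[j]))
                for i in range(2) for j in range(2) if P[i, j] > 0)
            got = mutual_information_from_joint(P)
            assert got == pytest.approx(oracle, abs=1e-9)

    def test_constant_variable_warns_zero(self):
        x = np.ones(100)
        y = np.arange(100.0)
        with pytest.warns(UserWarning):
            assert mutual_information(x, y) == 0.0

    def test_symmetry(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=500)
        y = x + rng.normal(size=500)
        assert mutual_information(x, y) == pytest.approx(
            mutual_information(y, x), abs=1e-12)

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            mutual_information(np.arange(5.0), np.arange(5.0))


class TestSAMI:
    def test_attention_rows_normalized(self):
        spec = TableSpec(n_samples=200, seed=0)
        X, y, _ = synth.generate_feature_table(spec)
        _, details = selection.sami_scores(X, y, return_details=True)
        assert np.allclose(details["attention"].sum(axis=1), 1.0, atol=1e-9)
        assert np.allclose(details["mi_matrix"],
                           details["mi_matrix"].T, atol=1e-12)

    def test_noise_scores_below_informative(self):
        spec = TableSpec(n_samples=500, effect_size=1.5, n_informative=3,
                         n_redundant=0, n_noise=5, seed=0)
        X, y, mask = synth.generate_feature_table(spec)
        scores = selection.sami_scores(X, y)
        assert scores[~mask].max() <= scores[mask].min()

    def test_permutation_equivariance(self):
        spec = TableSpec(n_samples=150, seed=4)
        X, y, _ = synth.generate_feature_table(spec)
        proj = AttentionProjections.create(X.shape[0], seed=0)
        base = selection.sami_scores(X, y, projections=proj)
        perm = np.random.default_rng(5).permutation(X.shape[1])
        permuted = selection.sami_scores(X[:, perm], y, projections=proj)
        assert np.allclose(permuted, base[perm], atol=1e-9)

    def test_dk_exceeding_n_rejected(self):
        with pytest.raises(ValueError):
            AttentionProjections.create(10, d_k=20)


class TestSelectKBest:
    def test_full_grid_degenerate(self):
        spec = TableSpec(n_samples=100, n_informative=2, n_redundant=0,
                         n_noise=2, seed=0)
        X, y, _ = synth.generate_feature_table(spec)
        scores = selection.sami_scores(X, y)
        sel = selection.select_k_best(X, y, scores, [4], mlp_config=FAST_MLP)
        assert sel.chosen_k == 4
        assert len(sel.selected) == 4

    def test_accuracies_contract(self):
        spec = TableSpec(n_samples=120, seed=1)
        X, y, _ = synth.generate_feature_table(spec)
        scores = selection.sami_scores(X, y)
        sel = selection.select_k_best(X, y, scores, [2, 4],
                                      mlp_config=FAST_MLP)
        assert set(sel.cv_accuracies) == {2, 4}
        assert all(0.0 <= v <= 1.0 for v in sel.cv_accuracies.values())
        assert sel.chosen_k in (2, 4)

    def test_bad_grid_rejected(self):
        X = np.random.default_rng(0).random((50, 4))
        y = (np.arange(50) % 2)
        with pytest.raises(ValueError):
            selection.select_k_best(X, y, np.ones(4), [])
        with pytest.raises(ValueError):
            selection.select_k_best(X, y, np.ones(4), [1, 2])
        with pytest.raises(ValueError):
            selection.select_k_best(X, y, np.ones(4), [5])


class TestFuse:
    def test_widths(self):
        n = 10
        hand6 = pd.DataFrame(np.random.default_rng(0).random((n, 6)),
                             columns=[f"h{i}" for i in range(6)])
        hand8 = pd.DataFrame(np.random.default_rng(1).random((n, 8)),
                             columns=[f"h{i}" for i in range(8)])
        deep = pd.DataFrame(np.random.default_rng(2).random((n, 2048)),
                            columns=[f"f{i:04d}" for i in range(2048)])
        assert selection.fuse(hand6, deep).data.shape[1] == 2054
        assert selection.fuse(hand8, deep).data.shape[1] == 2056

    def test_row_order_and_provenance(self):
        n = 8
        hand = pd.DataFrame({"h0": np.arange(float(n))})
        deep = pd.DataFrame({"f0": np.arange(float(n)) * 2})
        fused = selection.fuse(hand, deep)
        assert list(fused.data.index) == list(range(n))
        assert fused.provenance == ["handcrafted", "deep"]
        # z-scored columns preserve ordering
        assert (np.diff(fused.data["h0"].to_numpy()) > 0).all()

    def test_id_mismatch_rejected(self):
        hand = pd.DataFrame({"h0": np.arange(4.0)}, index=[0, 1, 2, 3])
        deep = pd.DataFrame({"f0": np.arange(4.0)}, index=[0, 1, 2, 9])
        with pytest.raises(ValueError):
            selection.fuse(hand, deep)

    def test_train_mask_statistics(self):
        hand = pd.DataFrame({"h0": [0.0, 1.0, 2.0, 100.0]})
        deep = pd.DataFrame({"f0": [0.0, 0.0, 0.0, 0.0]})
        mask = np.array([True, True, True, False])
        fused = selection.fuse(hand, deep, train_mask=mask)
        train_part = fused.data["h0"].to_numpy()[:3]
        assert train_part.mean() == pytest.approx(0.0, abs=1e-12)


class TestRelevance:
    def test_zero_weights_half(self):
        spec = TableSpec(n_samples=100, seed=0)
        X, y, _ = synth.generate_feature_table(spec)
        R = selection.relevance_scores(X, y, 0.0, 0.0, 0.0)
        assert np.allclose(R, 0.5, atol=1e-12)

    def test_duplicate_column_penalized(self):
        rng = np.random.default_rng(0)
        n = 400
        y = (np.arange(n) % 2)
        base = rng.normal(size=n) + 1.0 * y
        X = np.column_stack([base, base.copy(), rng.normal(size=n) + 1.0 * y])
        stats = selection.compute_relevance_stats(X, y)
        assert stats.redundancy[0] == pytest.approx(1.0)
        assert stats.redundancy[1] == pytest.approx(1.0)
        R = selection.relevance_scores(X, y, 0.5, 0.0, 0.8, stats=stats)
        assert R[0] < R[2] and R[1] < R[2]

    def test_range_and_monotonicity(self):
        stats = selection.RelevanceStats(
            mi=np.array([0.2, 0.2]), variance=np.array([0.5, 0.5]),
            redundancy=np.array([0.1, 0.9]))
        X = np.random.default_rng(1).random((50, 2))
        y = np.arange(50) % 2
        R = selection.relevance_scores(X, y, 0.5, 0.5, 0.5, stats=stats)
        assert np.all((R > 0) & (R < 1))
        assert R[0] > R[1]  # higher redundancy -> lower score

    def test_invalid_weights_rejected(self):
        X = np.random.default_rng(2).random((30, 3))
        y = np.arange(30) % 2
        with pytest.raises(ValueError):
            selection.relevance_scores(X, y, 1.5, 0.0, 0.0)

    def test_single_feature_rejected(self):
        with pytest.raises(ValueError):
            selection.compute_relevance_stats(
                np.random.default_rng(0).random((30, 1)), np.arange(30) % 2)


class TestUpdateParam:
    def test_no_accuracy_change(self):
        assert selection.update_param(0.4, 0.2, 0.7, 0.7) == 0.4

    def test_spec_arithmetic(self):
        got = selection.update_param(0.5, 0.3, 0.8, 0.7)
        assert got == pytest.approx(0.5002, abs=1e-12)

    def test_clipping(self):
        assert selection.update_param(1.0, 0.0, 2.0, 0.0, eta=10.0) == 1.0
        assert selection.update_param(0.0, 1.0, 2.0, 0.0, eta=10.0) == 0.0


def _splits(n, seed=0):
    rng = np.random.default_rng(seed)
    idx = rng.permutation(n)
    n_tr, n_va = int(0.7 * n), int(0.1 * n)
    return {"train": idx[:n_tr], "val": idx[n_tr:n_tr + n_va],
            "test": idx[n_tr + n_va:]}


class TestOFS:
    def _run(self, spec, n_iter=8, seed=0):
        X, y, _ = synth.generate_feature_table(spec)
        fused = pd.DataFrame(X, columns=[f"c{i}" for i in range(X.shape[1])])
        return selection.ofs_search(fused, y, _splits(len(y)), n_iter=n_iter,
                                    seed=seed, mlp_config=FAST_MLP)

    def test_best_so_far_non_decreasing(self):
        res = self._run(TableSpec(n_samples=200, seed=0))
        best_curve = np.maximum.accumulate(res.history)
        assert res.val_accuracy == pytest.approx(best_curve[-1])
        assert len(res.history) <= 8

    def test_deterministic(self):
        spec = TableSpec(n_samples=200, seed=1)
        a = self._run(spec, seed=3)
        b = self._run(spec, seed=3)
        assert a.trajectory == b.trajectory
        assert (a.alpha, a.beta, a.gamma, a.k) == (b.alpha, b.beta, b.gamma,
                                                   b.k)
        assert a.selected == b.selected

    def test_null_table_chance_level(self):
        spec = TableSpec(n_samples=800, n_informative=0, n_redundant=0,
                         n_noise=8, seed=0)
        res = self._run(spec, n_iter=10)
        assert 0.4 <= res.val_accuracy <= 0.6

    def test_selected_names_resolve(self):
        res = self._run(TableSpec(n_samples=200, seed=2))
        assert len(res.selected) == res.k
        assert all(name.startswith("c") for name in res.selected)
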