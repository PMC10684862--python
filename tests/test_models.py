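"""DEG filtering, SVM-RFE, plateau rule, grid search, evaluation, importance."""

import numpy as np
import pandas as pd
import pytest

from oracles import auc_pair_counting
from oxim import models as md


def _binary_planted(rng, n=200, n_genes=10, informative=(3,), delta=0.4):
    y = rng.integers(0, 2, n)
    p = np.full((n, n_genes), 0.5)
    for j in informative:
        p[:, j] = np.where(y == 1, 0.5 + delta / 2, 0.5 - delta / 2)
    X = (rng.random((n, n_genes)) < p).astype(float)
    return X, y


class TestFilterDegs:
    def _diff(self):
        return pd.DataFrame(
            {
                "gene": ["a", "b", "c", "d"],
                "log2fc": [0.5, 1.19, 0.9, -2.0],
                "p": [0.001] * 4,
                "p_adj": [0.001, 0.0005, 0.2, 0.0001],
            }
        )

    def test_strict_boundaries_and_sorting(self):
        out = md.filter_degs(self._diff())
        assert out == ["b"]  # a: lfc not > 0.5; c: padj >= 0.05; d: negative lfc

    def test_empty_result_warns(self):
        diff = pd.DataFrame({"gene": ["a"], "log2fc": [0.1], "p": [0.5], "p_adj": [0.9]})
        with pytest.warns(UserWarning):
            assert md.filter_degs(diff) == []


class TestSvmRfe:
    def test_informative_gene_ranked_first(self, rng):
        hits = 0
        for seed in range(10):
            r = np.random.default_rng(seed)
            X, y = _binary_planted(r, n=200, n_genes=10, informative=(3,), delta=0.8)
            ranked = md.svm_rfe_rank(X, y, [f"g{i}" for i in range(10)], seed=seed)
            hits += ranked[0] == "g3"
        assert hits >= 9

    def test_two_genes_returns_permutation(self, rng):
        X, y = _binary_planted(rng, n=50, n_genes=2, informative=(0,))
        ranked = md.svm_rfe_rank(X, y, ["a", "b"])
        assert sorted(ranked) == ["a", "b"]

    def test_duplicated_genes_get_adjacent_ranks(self, rng):
        X, y = _binary_planted(rng, n=100, n_genes=3, informative=(0,), delta=0.6)
        X = np.column_stack([X[:, 0], X[:, 0], X[:, 1]])  # dup the informative gene
        ranked = md.svm_rfe_rank(X, y, ["dupA", "dupB", "noise"], seed=0)
        ia, ib = ranked.index("dupA"), ranked.index("dupB")
        assert abs(ia - ib) == 1
        assert ia < ib  # tie broken by name: earlier name ranks better

    def test_column_order_invariance(self, rng):
        X, y = _binary_planted(rng, n=150, n_genes=6, informative=(1, 4), delta=0.7)
        names = [f"g{i}" for i in range(6)]
        ranked1 = md.svm_rfe_rank(X, y, names, seed=0)
        perm = [3, 0, 5, 1, 4, 2]
        ranked2 = md.svm_rfe_rank(X[:, perm], y, [names[i] for i in perm], seed=0)
        assert ranked1 == ranked2

    def test_single_class_error(self):
        with pytest.raises(ValueError):
            md.svm_rfe_rank(np.zeros((10, 3)), np.zeros(10), ["a", "b", "c"])


class TestPlateauRule:
    def test_worked_curve(self):
        sizes = [3, 6, 9, 12, 15, 18]
        acc = [0.70, 0.74, 0.77, 0.78, 0.781, 0.779]
        assert md.choose_plateau_size(sizes, acc, 0.005) == 12

    def test_monotone_big_jumps_chooses_largest(self):
        assert md.choose_plateau_size([3, 6, 9], [0.6, 0.7, 0.8], 0.005) == 9

    def test_flat_curve_chooses_smallest(self):
        assert md.choose_plateau_size([3, 6, 9], [0.75, 0.75, 0.75], 0.005) == 3

    def test_select_size_drops_oversized_candidates(self, rng):
        X, y = _binary_planted(rng, n=120, n_genes=5, informative=(0, 1), delta=0.8)
        with pytest.warns(UserWarning):
            sel = md.select_size(X, y, [f"g{i}" for i in range(5)], sizes=(3, 6, 9))
        assert sel.sizes == [3]
        assert sel.chosen_size == 3


class TestGridSearch:
    def test_single_point_grid_returned(self, rng):
        X, y = _binary_planted(rng, n=80, n_genes=4, informative=(0,), delta=0.8)
        gs = md.cv_grid_search(X, y, "DT", grid={"cp": [0.01]}, replicates=2, seed=1)
        assert gs.best_params == {"cp": 0.01}

    def test_separable_data_reaches_high_accuracy(self, rng):
        n = 120
        y = rng.integers(0, 2, n)
        X = np.column_stack([y + 0.01 * rng.normal(size=n), rng.normal(size=n)])
        gs = md.cv_grid_search(X, y, "SVM", replicates=2, seed=2)
        assert gs.best_accuracy >= 0.99
        assert gs.best_auc >= 0.99

    def test_deterministic_under_seed(self, rng):
        X, y = _binary_planted(rng, n=100, n_genes=5, informative=(2,), delta=0.6)
        g1 = md.cv_grid_search(X, y, "RF", grid={"mtry": [2, 3]}, replicates=2, seed=7)
        g2 = md.cv_grid_search(X, y, "RF", grid={"mtry": [2, 3]}, replicates=2, seed=7)
        assert g1.best_params == g2.best_params
        pd.testing.assert_frame_equal(g1.table, g2.table)

    def test_empty_grid_error(self, rng):
        X, y = _binary_planted(rng)
        with pytest.raises(ValueError):
            md.cv_grid_search(X, y, "DT", grid={"cp": []})


class TestTrainEvaluate:
    def test_train_predict_separable(self, rng):
        n = 100
        y = rng.integers(0, 2, n)
        X = np.column_stack([y * 2.0, rng.normal(size=n)])
        for family, params in [
            ("DT", {"cp": 0.005}), ("SVM", {"sigma": 0.1, "C": 1}),
            ("ANN", {"size": 3, "decay": 0.1}), ("RF", {"mtry": 2}),
        ]:
            model = md.train_final(X, y, family, params, genes=["a", "b"], seed=0)
            ev = md.evaluate(model, X, y)
            assert ev.accuracy == 1.0 and ev.auc == 1.0

    def test_rf_split_candidates_match_mtry(self, rng):
        X, y = _binary_planted(rng, n=100, n_genes=12, informative=(0, 5), delta=0.6)
        model = md.train_final(X, y, "RF", {"mtry": 3}, genes=[f"g{i}" for i in range(12)])
        assert model.estimator.max_features == 3

    def test_unknown_family_error(self, rng):
        X, y = _binary_planted(rng)
        with pytest.raises(ValueError):
            md.train_final(X, y, "XGB", {}, genes=[])

    def test_gene_count_mismatch_error(self, rng):
        X, y = _binary_planted(rng, n_genes=3, informative=(0,))
        model = md.train_final(X, y, "DT", {"cp": 0.01}, genes=["a", "b", "c"])
        with pytest.raises(ValueError):
            md.evaluate(model, X[:, :2], y)


class TestAuc:
    def test_worked_example(self):
        assert md.auc_score(np.array([0.1, 0.4, 0.35, 0.8]), np.array([0, 0, 1, 1])) == 0.75

    def test_all_equal_scores_half(self):
        assert md.auc_score(np.ones(6), np.array([0, 1, 0, 1, 0, 1])) == 0.5

    def test_matches_pair_counting(self, rng):
        """Rank-formula AUC equals brute-force pair counting, n <= 30, with ties."""
        for _ in range(40):
            n = int(rng.integers(4, 31))
            y = rng.integers(0, 2, n)
            if y.sum() in (0, n):
                y[0] = 1 - y[0]
            scores = np.round(rng.random(n), 1)  # coarse grid forces ties
            assert md.auc_score(scores, y) == pytest.approx(auc_pair_counting(scores, y))


class TestImportance:
    def test_gene_identical_to_label(self, rng):
        y = rng.integers(0, 2, 50)
        X = np.column_stack([y.astype(float), rng.normal(size=50)])
        imp = md.importance(X, y, ["label_gene", "noise"])
        assert imp["label_gene"] == 1.0
        assert imp.index[0] == "label_gene"

    def test_independent_gene_near_half(self, rng):
        y = rng.integers(0, 2, 4000)
        X = rng.normal(size=(4000, 1))
        imp = md.importance(X, y, ["g"])
        assert imp["g"] == pytest.approx(0.5, abs=0.05)

    def test_binary_gene_matches_pair_oracle(self, rng):
        y = np.array([1] * 50 + [0] * 50)
        x = np.concatenate([(rng.random(50) < 0.74), (rng.random(50) < 0.26)]).astype(float)
        imp = md.importance(x[:, None], y, ["g"])
        expected = auc_pair_counting(x, y)
        assert imp["g"] == pytest.approx(max(expected, 1 - expected))
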