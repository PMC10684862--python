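"""Binary differential expression, BH adjustment, GMT parsing, preranked GSEA."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from oracles import fisher_two_sided, gsea_es_bruteforce
from oxim.diffgsea import (
    bh_adjust,
    binary_de,
    enrichment_score,
    gsea_preranked,
    label_subtypes,
    make_ranking,
    read_gmt,
)


class TestBinaryDE:
    def _matrix_from_counts(self, ones_a, n_a, ones_b, n_b):
        row = np.array([1] * ones_a + [0] * (n_a - ones_a) + [1] * ones_b + [0] * (n_b - ones_b))
        labels = np.array(["A"] * n_a + ["B"] * n_b)
        return row[None, :], labels

    def test_fisher_example_table(self):
        # 2x2 table [[3,1],[1,3]]: exact two-sided p = 34/70
        vals, labels = self._matrix_from_counts(3, 4, 1, 4)
        out = binary_de(vals, labels, group_order=("A", "B"))
        assert out["p"][0] == pytest.approx(34 / 70)

    def test_equal_proportions_zero_lfc(self):
        vals, labels = self._matrix_from_counts(2, 4, 2, 4)
        out = binary_de(vals, labels)
        assert out["log2fc"][0] == 0.0

    def test_lfc_formula(self):
        # prop_a=0.8, prop_b=0.2 with eps=0.01 -> log2(0.81/0.21)
        vals, labels = self._matrix_from_counts(8, 10, 2, 10)
        out = binary_de(vals, labels, group_order=("A", "B"))
        assert out["log2fc"][0] == pytest.approx(np.log2(0.81 / 0.21))

    def test_more_than_two_labels_error(self):
        vals = np.zeros((1, 6), dtype=int)
        with pytest.raises(ValueError):
            binary_de(vals, np.array(["A", "A", "B", "B", "C", "C"]))

    def test_fisher_matches_enumeration_on_random_tables(self, rng):
        """Exact-p agreement with hypergeometric enumeration, tables up to n=40."""
        for _ in range(60):
            n_a = int(rng.integers(2, 21))
            n_b = int(rng.integers(2, 21))
            ones_a = int(rng.integers(0, n_a + 1))
            ones_b = int(rng.integers(0, n_b + 1))
            vals, labels = self._matrix_from_counts(ones_a, n_a, ones_b, n_b)
            out = binary_de(vals, labels, group_order=("A", "B"))
            expected = fisher_two_sided(ones_a, n_a - ones_a, ones_b, n_b - ones_b)
            assert out["p"][0] == pytest.approx(expected, rel=1e-9)


class TestBHAdjust:
    def test_single_p_unchanged(self):
        assert bh_adjust([0.03])[0] == pytest.approx(0.03)

    def test_step_up_recursion(self):
        np.testing.assert_allclose(bh_adjust([0.01, 0.02, 0.03, 0.04]), [0.04] * 4)

    def test_all_ones(self):
        np.testing.assert_allclose(bh_adjust([1.0, 1.0, 1.0]), 1.0)

    def test_out_of_range_error(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])

    @settings(max_examples=40, deadline=None)
    @given(st.lists(st.floats(min_value=0, max_value=1), min_size=2, max_size=20))
    def test_order_invariance_and_dominance(self, ps):
        adj = bh_adjust(ps)
        perm = np.random.RandomState(0).permutation(len(ps))
        adj_perm = bh_adjust(np.asarray(ps)[perm])
        np.testing.assert_allclose(adj[perm], adj_perm)
        assert (adj >= np.asarray(ps) - 1e-12).all()
        assert (adj <= 1 + 1e-12).all()


class TestReadGmt:
    def test_basic_and_dedup(self, tmp_path):
        p = tmp_path / "sets.gmt"
        p.write_text("SET1\tdesc\tA\tB\nSET2\tdesc\tB\tB\tC\n")
        sets = read_gmt(p)
        assert sets == {"SET1": ["A", "B"], "SET2": ["B", "C"]}

    def test_short_line_error_has_lineno(self, tmp_path):
        p = tmp_path / "bad.gmt"
        p.write_text("SET1\tdesc\tA\nONLYNAME\n")
        with pytest.raises(ValueError, match="2"):
            read_gmt(p)


class TestEnrichmentScore:
    def test_top_gene_singleton_set(self):
        stats_sorted = np.array([3.0, 2.0, 1.0, 0.5, -1.0])
        mask = np.array([True, False, False, False, False])
        assert enrichment_score(stats_sorted, mask) == pytest.approx(1.0)

    def test_matches_bruteforce_oracle(self, rng):
        """ES equals the explicit running-sum maximum, tol 1e-12."""
        for _ in range(40):
            stats_sorted = -np.sort(-rng.normal(size=50))
            idx = rng.choice(50, size=5, replace=False)
            mask = np.zeros(50, dtype=bool)
            mask[idx] = True
            fast = enrichment_score(stats_sorted, mask)
            slow = gsea_es_bruteforce(stats_sorted, mask)
            assert fast == pytest.approx(slow, abs=1e-12)

    def test_es_bounds(self, rng):
        for _ in range(20):
            stats_sorted = -np.sort(-rng.normal(size=30))
            mask = np.zeros(30, dtype=bool)
            mask[rng.choice(30, size=6, replace=False)] = True
            es = enrichment_score(stats_sorted, mask)
            assert -1 - 1e-12 <= es <= 1 + 1e-12


class TestGseaPreranked:
    def _ranking(self, rng, n=60):
        stats_vals = rng.normal(size=n)
        return pd.Series(stats_vals, index=[f"g{i}" for i in range(n)])

    def test_sign_flip_symmetry(self, rng):
        ranking = self._ranking(rng)
        sets = {"S1": [f"g{i}" for i in range(0, 10)], "S2": [f"g{i}" for i in range(20, 28)]}
        out_pos = gsea_preranked(ranking, sets, n_perm=100, seed=3)
        out_neg = gsea_preranked(-ranking, sets, n_perm=100, seed=3)
        merged = out_pos.merge(out_neg, on="name", suffixes=("_p", "_n"))
        assert (np.sign(merged["es_p"]) == -np.sign(merged["es_n"])).all()

    def test_planted_set_detected(self, rng):
        ranking = self._ranking(rng).sort_values(ascending=False)
        top = list(ranking.index[:8])
        sets = {"TOP": top, "RAND": [f"g{i}" for i in range(30, 40)]}
        out = gsea_preranked(ranking, sets, n_perm=300, seed=1).set_index("name")
        assert out.loc["TOP", "nes"] > 0
        assert out.loc["TOP", "p"] < 0.05
        assert abs(out.loc["RAND", "nes"]) < out.loc["TOP", "nes"]

    def test_absent_set_skipped(self, rng):
        ranking = self._ranking(rng)
        out = gsea_preranked(ranking, {"MISSING": ["zz1", "zz2"]}, n_perm=50, seed=0)
        assert out.empty


class TestLabelSubtypes:
    def _enr(self, ox_nes, im_nes):
        return pd.DataFrame(
            {"name": ["OXSET", "IMSET"], "es": [ox_nes / 3, im_nes / 3],
             "nes": [ox_nes, im_nes], "p": [0.01, 0.01], "p_adj": [0.02, 0.02]}
        )

    def test_positive_ox_marker_names_first_cluster_ox(self):
        mapping = label_subtypes(self._enr(3.3, -2.6), ["OXSET"], ["IMSET"], ("A", "B"))
        assert mapping == {"A": "OX+", "B": "IM+"}

    def test_swapped_inputs_swap_labels(self):
        mapping = label_subtypes(self._enr(-3.3, 2.6), ["OXSET"], ["IMSET"], ("A", "B"))
        assert mapping == {"A": "IM+", "B": "OX+"}

    def test_missing_marker_error(self):
        with pytest.raises(ValueError):
            label_subtypes(self._enr(1, -1), ["NOPE"], ["IMSET"])

    def test_tie_falls_back_to_immune_markers(self):
        mapping = label_subtypes(self._enr(0.0, -2.0), ["OXSET"], ["IMSET"], ("A", "B"))
        assert mapping == {"A": "OX+", "B": "IM+"}


def test_make_ranking_orders_by_lfc_then_p_then_name():
    diff = pd.DataFrame(
        {
            "gene": ["a", "b", "c", "d"],
            "log2fc": [1.0, 2.0, 1.0, 1.0],
            "p": [0.5, 0.1, 0.01, 0.01],
            "p_adj": [0.5, 0.2, 0.05, 0.05],
        }
    )
    ranking = make_ranking(diff)
    assert list(ranking.index) == ["b", "c", "d", "a"]
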