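"""Per-sample gene-set scoring, purity mapping, and rank-sum comparisons."""

import numpy as np
import pandas as pd
import pytest

from oracles import wilcoxon_exact_two_sided
from oxim.scores import (
    PURITY_A,
    checkpoint_compare,
    estimate_scores,
    marker_scores,
    ssgsea,
    wilcoxon_compare,
)
from oxim.cohorts import ExpressionMatrix


class TestSsgsea:
    def test_alpha_zero_matches_hand_ecdf_sum(self):
        # 5 genes, one sample, values give ranks 1..5 with set = top-2 genes.
        vals = np.array([[5.0], [4.0], [3.0], [2.0], [1.0]])
        genes = ["a", "b", "c", "d", "e"]
        # order by decreasing rank: a,b,c,d,e; hits at positions 1,2
        # ecdf_in = [.5, 1, 1, 1, 1]; ecdf_out = [0, 0, 1/3, 2/3, 1]
        expected = (0.5 - 0) + (1 - 0) + (1 - 1 / 3) + (1 - 2 / 3) + (1 - 1)
        s = ssgsea(vals, ["a", "b"], alpha=0.0, genes=genes)
        assert s.iloc[0] == pytest.approx(expected)

    def test_monotone_in_set_gene_values(self, rng):
        vals = rng.normal(size=(20, 1))
        genes = [f"g{i}" for i in range(20)]
        s0 = ssgsea(vals, ["g0", "g1"], genes=genes).iloc[0]
        boosted = vals.copy()
        boosted[[0, 1], 0] += 100.0  # push set genes to the top
        s1 = ssgsea(boosted, ["g0", "g1"], genes=genes).iloc[0]
        assert s1 >= s0

    def test_identical_rank_vectors_equal_scores(self):
        col = np.array([3.0, 1.0, 2.0, 5.0, 4.0])
        vals = np.stack([col, col * 10 + 2], axis=1)  # same ranks
        s = ssgsea(vals, ["g0", "g3"], genes=[f"g{i}" for i in range(5)])
        assert s.iloc[0] == pytest.approx(s.iloc[1])

    def test_empty_intersection_error(self, rng):
        with pytest.raises(ValueError):
            ssgsea(rng.normal(size=(4, 2)), ["nope"], genes=["a", "b", "c", "d"])


class TestEstimateScores:
    def test_additivity_and_purity_at_zero(self, rng):
        vals = rng.normal(size=(30, 5))
        genes = [f"g{i}" for i in range(30)]
        out = estimate_scores(vals, ["g0", "g1", "g2"], ["g10", "g11"], genes=genes)
        np.testing.assert_allclose(
            out["estimate_score"], out["immune_score"] + out["stromal_score"]
        )
        assert np.cos(PURITY_A) == pytest.approx(0.82251, abs=1e-4)
        assert ((out["tumor_purity"] >= 0) & (out["tumor_purity"] <= 1)).all()

    def test_purity_decreasing_in_estimate(self, rng):
        vals = rng.normal(size=(30, 8))
        genes = [f"g{i}" for i in range(30)]
        out = estimate_scores(vals, ["g0", "g1"], ["g2", "g3"], genes=genes).sort_values(
            "estimate_score"
        )
        assert (np.diff(out["tumor_purity"]) <= 1e-12).all()

    def test_immune_score_separates_planted_subtypes(self, small_merged):
        """IM+ samples outscore OX+ on the immune signature (rank-sum p < 0.01)."""
        merged, _, truth = small_merged
        labels = np.array([truth.subtype[s] for s in merged.samples])
        im_sig = [g for g in truth.informative_genes if g in merged.genes][40:]  # IM program
        out = estimate_scores(merged.values, im_sig[:20], im_sig[20:30], genes=merged.genes)
        stat, p = wilcoxon_compare(out["immune_score"].to_numpy(), labels)
        assert p < 0.01
        med = pd.Series(out["immune_score"].to_numpy()).groupby(labels).median()
        assert med["IM+"] > med["OX+"]


class TestMarkerScores:
    def test_proportion_of_ones(self):
        vals = np.array([[1], [0], [1], [0]])
        out = marker_scores(vals, {"pop": ["g0", "g1", "g2"]}, genes=["g0", "g1", "g2", "g3"])
        assert out["pop"].iloc[0] == pytest.approx(2 / 3)

    def test_invariant_to_non_marker_genes(self, rng):
        vals = (rng.random((10, 4)) > 0.5).astype(float)
        sets = {"pop": ["g0", "g1"]}
        out1 = marker_scores(vals, sets, genes=[f"g{i}" for i in range(10)])
        vals2 = vals.copy()
        vals2[5:, :] = 1 - vals2[5:, :]
        out2 = marker_scores(vals2, sets, genes=[f"g{i}" for i in range(10)])
        pd.testing.assert_frame_equal(out1, out2)

    def test_absent_population_omitted(self):
        vals = np.ones((2, 2))
        out = marker_scores(vals, {"ok": ["g0"], "gone": ["zz"]}, genes=["g0", "g1"])
        assert list(out.columns) == ["ok"]


class TestWilcoxon:
    def test_exact_small_sample(self):
        stat, p = wilcoxon_compare([1, 2, 3, 4, 5, 6], ["a", "a", "a", "b", "b", "b"])
        assert p == pytest.approx(0.1)

    def test_identical_groups_p_one(self):
        _, p = wilcoxon_compare([1, 2, 3, 1, 2, 3], ["a", "a", "a", "b", "b", "b"])
        assert p == pytest.approx(1.0)

    def test_exact_agrees_with_enumeration(self, rng):
        """Exact path matches brute-force enumeration for combined n <= 10."""
        for _ in range(25):
            nx = int(rng.integers(2, 6))
            ny = int(rng.integers(2, 6))
            pooled = rng.permutation(np.arange(1.0, nx + ny + 1.0))  # distinct values
            x, y = pooled[:nx], pooled[nx:]
            groups = ["a"] * nx + ["b"] * ny
            _, p = wilcoxon_compare(np.concatenate([x, y]), groups)
            assert p == pytest.approx(wilcoxon_exact_two_sided(x, y), rel=1e-9)

    def test_exact_and_normal_paths_agree(self, rng):
        from scipy.stats import mannwhitneyu

        x = rng.normal(size=15)
        y = rng.normal(loc=0.8, size=15)  # combined n=30 -> asymptotic path
        vals = np.concatenate([x, y])
        groups = np.array(["a"] * 15 + ["b"] * 15)
        _, p_approx = wilcoxon_compare(vals, groups)
        p_exact = mannwhitneyu(x, y, alternative="two-sided", method="exact").pvalue
        assert abs(p_approx - p_exact) < 0.02

    def test_empty_group_error(self):
        with pytest.raises(ValueError):
            wilcoxon_compare([1.0, 2.0], ["a", "a"])


class TestCheckpointCompare:
    def _cohort(self, rng, cid, genes, n=30):
        return ExpressionMatrix(
            cohort_id=cid,
            genes=genes,
            samples=[f"s{i}" for i in range(n)],
            values=rng.normal(size=(len(genes), n)),
        )

    def test_missing_gene_flagged_not_error(self, rng):
        m = self._cohort(rng, "c1", ["PDCD1", "OTHER"])
        labels = {f"c1_s{i}": ("OX+" if i % 2 else "IM+") for i in range(30)}
        out = checkpoint_compare([m], labels)
        row = out[out["gene"] == "CTLA4"].iloc[0]
        assert bool(row["missing"])
        assert not out[out["gene"] == "PDCD1"]["missing"].iloc[0]

    def test_planted_immune_checkpoint_higher_in_im(self, small_compendium):
        """CTLA4/PDCD1 sit in the immune program: IM+ should be higher per cohort."""
        matrices, _, truth = small_compendium
        out = checkpoint_compare(matrices, truth.subtype)
        ok = out[~out["missing"]]
        sig = ok[ok["p"] < 0.05]
        assert len(sig) > 0
        assert (sig["higher_in"] == "IM+").mean() > 0.9

    def test_shuffled_labels_near_nominal(self, rng):
        ms = [self._cohort(rng, f"c{j}", ["PDCD1", "CTLA4"], n=40) for j in range(10)]
        labels = {}
        for m in ms:
            for i, s in enumerate(m.samples):
                labels[f"{m.cohort_id}_{s}"] = "OX+" if rng.random() < 0.5 else "IM+"
        out = checkpoint_compare(ms, labels)
        assert (out["p"] < 0.05).mean() < 0.25
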