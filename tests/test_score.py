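import numpy as np
import pandas as pd
import pytest

from agesig import (
    compute_gene_score,
    kruskal_wallis,
    posthoc_mw_holm,
    regress_score,
    wilcoxon_compare,
)
from agesig.containers import GeneScoreResult
from agesig.score import holm_adjust
from conftest import build_matrix, build_samples
from test_preprocess import make_signature


def scores_from(values, groups=None):
    """Wrap raw score values directly (for the statistics helpers)."""
    ids = [f"s{i}" for i in range(len(values))]
    frame = pd.DataFrame(
        {"raw_score": values, "scaled_score": values},
        index=pd.Index(ids, name="sample_id"),
    )
    result = GeneScoreResult(frame, n_genes_used=1, genes_used=["g"])
    labels = build_samples(dict(zip(ids, groups))) if groups else None
    return result, labels


class TestGeneScore:
    def test_single_down_gene_definition(self):
        # highest expression -> rank 1 (young-like); lowest -> rank n
        m = build_matrix([[9.0, 5.0, 2.0]])
        sig = make_signature([("g1", "down", 0.9)])
        res = compute_gene_score(m, sig)
        assert np.allclose(res.scores["raw_score"], [1, 2, 3])
        assert np.allclose(res.scores["scaled_score"], [1 / 3, 2 / 3, 1.0])

    def test_lowest_expressing_subject_gets_rank_n(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=108)
        m = build_matrix(x[None, :])
        res = compute_gene_score(m, make_signature([("g1", "down", 0.9)]))
        assert res.scores["raw_score"].iloc[int(np.argmin(x))] == 108
        assert res.scores["scaled_score"].iloc[int(np.argmin(x))] == 1.0

    def test_two_gene_median_hand_enumeration(self):
        # down gene (3,2,1) and up gene (1,2,3) give identical per-gene ranks
        m = build_matrix([[3.0, 2.0, 1.0], [1.0, 2.0, 3.0]])
        sig = make_signature([("g1", "down", 0.9), ("g2", "up", 0.9)])
        res = compute_gene_score(m, sig)
        assert np.allclose(res.scores["raw_score"], [1, 2, 3])

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(1)
        arr = rng.normal(8, 1, size=(10, 15))
        sig = make_signature(
            [(f"g{i + 1}", "down" if i % 2 else "up", 0.9) for i in range(10)]
        )
        base = compute_gene_score(build_matrix(arr), sig)
        transformed = np.empty_like(arr)
        for i in range(10):  # a different strictly increasing map per gene
            transformed[i] = np.exp(arr[i] / (i + 1)) + i
        res = compute_gene_score(build_matrix(transformed), sig)
        pd.testing.assert_frame_equal(res.scores, base.scores)

    def test_rank_sum_conservation(self):
        rng = np.random.default_rng(2)
        n = 12
        arr = rng.normal(size=(5, n))
        arr[0, :4] = arr[0, 0]  # force ties
        sig = make_signature([(f"g{i + 1}", "down", 0.9) for i in range(5)])
        m = build_matrix(arr)
        # recompute per-gene ranks the way the score does and check the sum
        from scipy.stats import rankdata
        for i in range(5):
            assert rankdata(-arr[i]).sum() == n * (n + 1) / 2

    def test_ties_get_average_ranks(self):
        m = build_matrix([[5.0, 5.0, 1.0]])
        res = compute_gene_score(m, make_signature([("g1", "down", 0.9)]))
        assert np.allclose(res.scores["raw_score"], [1.5, 1.5, 3])

    def test_missing_genes_skipped_and_counted(self):
        m = build_matrix([[1.0, 2.0]])
        sig = make_signature([("g1", "down", 0.9), ("absent", "up", 0.9)])
        res = compute_gene_score(m, sig)
        assert res.n_genes_used == 1

    def test_no_genes_present_is_error(self):
        m = build_matrix([[1.0, 2.0]])
        with pytest.raises(ValueError, match="no signature genes"):
            compute_gene_score(m, make_signature([("absent", "down", 0.9)]))

    def test_sum_variant(self):
        m = build_matrix([[3.0, 2.0, 1.0], [1.0, 2.0, 3.0]])
        sig = make_signature([("g1", "down", 0.9), ("g2", "up", 0.9)])
        res = compute_gene_score(m, sig, method="sum")
        assert np.allclose(res.scores["raw_score"], [2, 4, 6])


class TestWilcoxon:
    def test_exact_small_sample(self):
        scores, labels = scores_from([1, 2, 3, 4, 5, 6], ["a"] * 3 + ["b"] * 3)
        cmp_ = wilcoxon_compare(scores, labels, "a", "b")
        assert cmp_.statistic == 0.0
        assert cmp_.p_value == pytest.approx(0.1)

    def test_identical_groups(self):
        scores, labels = scores_from([1, 2, 3, 1, 2, 3], ["a"] * 3 + ["b"] * 3)
        assert wilcoxon_compare(scores, labels, "a", "b").p_value == pytest.approx(1.0)

    def test_label_swap_symmetry(self):
        rng = np.random.default_rng(3)
        scores, labels = scores_from(rng.random(30), ["a"] * 15 + ["b"] * 15)
        ab = wilcoxon_compare(scores, labels, "a", "b")
        ba = wilcoxon_compare(scores, labels, "b", "a")
        assert ab.p_value == pytest.approx(ba.p_value)

    def test_empty_group_rejected(self):
        scores, labels = scores_from([1, 2], ["a", "a"])
        with pytest.raises(ValueError, match="empty or unknown"):
            wilcoxon_compare(scores, labels, "a", "b")


class TestKruskalWallis:
    def test_identical_groups_h_zero(self):
        scores, labels = scores_from([1, 2, 3] * 3, ["a", "a", "a", "b", "b", "b", "c", "c", "c"])
        # note: groups hold identical value multisets
        scores2, labels2 = scores_from([1, 2, 3, 1, 2, 3, 1, 2, 3],
                                       ["a", "a", "a", "b", "b", "b", "c", "c", "c"])
        cmp_ = kruskal_wallis(scores2, labels2)
        assert cmp_.statistic == pytest.approx(0.0)
        assert cmp_.p_value == pytest.approx(1.0)

    def test_textbook_formula_oracle(self):
        values = [1, 2, 3, 4, 5, 6]
        groups = ["a", "a", "b", "b", "c", "c"]
        scores, labels = scores_from(values, groups)
        cmp_ = kruskal_wallis(scores, labels)
        # no ties: H = 12/(N(N+1)) * sum n_i (Rbar_i - (N+1)/2)^2
        n_total = 6
        rbar = {"a": 1.5, "b": 3.5, "c": 5.5}
        h = 12 / (n_total * (n_total + 1)) * sum(
            2 * (rbar[g] - (n_total + 1) / 2) ** 2 for g in rbar
        )
        assert cmp_.statistic == pytest.approx(h)

    def test_single_group_rejected(self):
        scores, labels = scores_from([1, 2, 3], ["a", "a", "a"])
        with pytest.raises(ValueError, match="at least 2"):
            kruskal_wallis(scores, labels)


class TestHolm:
    def test_worked_example(self):
        assert np.allclose(holm_adjust([0.01, 0.03, 0.04]), [0.03, 0.06, 0.06])

    def test_single_comparison_unchanged(self):
        assert holm_adjust([0.2]) == pytest.approx([0.2])

    def test_all_ones(self):
        assert np.allclose(holm_adjust([1.0, 1.0, 1.0]), 1.0)

    def test_posthoc_pairs_and_monotonicity(self):
        rng = np.random.default_rng(4)
        values = np.concatenate([rng.random(8), rng.random(8) + 0.5, rng.random(8) + 1])
        scores, labels = scores_from(values, ["a"] * 8 + ["b"] * 8 + ["c"] * 8)
        comparisons = posthoc_mw_holm(scores, labels)
        assert len(comparisons) == 3
        ordered = sorted(comparisons, key=lambda c: c.p_value)
        adj = [c.adjusted_p for c in ordered]
        assert all(x <= y for x, y in zip(adj, adj[1:]))
        assert all(c.adjusted_p >= c.p_value for c in comparisons)


class TestRegression:
    def test_perfect_linear(self):
        scores, _ = scores_from(np.arange(10) * 0.1)
        cov = pd.Series(np.arange(10, dtype=float), index=scores.scores.index)
        fit = regress_score(scores, cov)
        assert fit["r_squared"] == pytest.approx(1.0)

    def test_slope_sign_flips_with_negated_covariate(self):
        rng = np.random.default_rng(5)
        scores, _ = scores_from(rng.random(20))
        cov = pd.Series(rng.normal(size=20), index=scores.scores.index)
        a = regress_score(scores, cov)
        b = regress_score(scores, -cov)
        assert a["slope"] == pytest.approx(-b["slope"])
        assert a["r_squared"] == pytest.approx(b["r_squared"])

    def test_null_p_values_roughly_uniform(self):
        from scipy import stats
        rng = np.random.default_rng(6)
        ps = []
        for _ in range(100):
            scores, _ = scores_from(rng.random(25))
            cov = pd.Series(rng.normal(size=25), index=scores.scores.index)
            ps.append(regress_score(scores, cov)["p_value"])
        assert stats.kstest(ps, "uniform").pvalue > 0.01

    def test_constant_covariate_rejected(self):
        scores, _ = scores_from([0.1, 0.2, 0.3, 0.4])
        cov = pd.Series(1.0, index=scores.scores.index)
        with pytest.raises(ValueError, match="constant"):
            regress_score(scores, cov)
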