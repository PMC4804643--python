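import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from crtpredict import (
    BinaryContrast,
    compute_feature_table,
    feature_scores_from_stats,
    minmax_norm,
    select_top_k,
    welch_t,
)
from crtpredict.errors import SelectionError, StatError


class TestWelchT:
    def test_hand_example(self):
        # means 2 vs 5, both variances 1: t = -3 / sqrt(2/3), df = 4
        t, df, p = welch_t((1, 2, 3), (4, 5, 6))
        assert t == pytest.approx(-3.674, abs=5e-4)
        assert df == pytest.approx(4.0)
        assert p == pytest.approx(0.0213, abs=5e-5)

    def test_identical_groups(self):
        t, _df, p = welch_t((2, 4, 6), (2, 4, 6))
        assert t == 0.0
        assert p == 1.0

    def test_degenerate_equal_constants(self):
        t, _df, p = welch_t((5, 5, 5), (5, 5, 5))
        assert t == 0.0
        assert p == 1.0

    def test_degenerate_unequal_constants(self):
        t, _df, p = welch_t((5, 5, 5), (6, 6, 6))
        assert t == -np.inf
        assert 0 < p <= 1e-300

    def test_small_group_rejected(self):
        with pytest.raises(StatError):
            welch_t((1,), (2, 3))

    def test_against_independent_oracle(self):
        # scipy's Welch implementation is an independent code path
        rng = np.random.default_rng(123)
        for _ in range(100):
            nx = rng.integers(2, 12)
            ny = rng.integers(2, 12)
            x = rng.normal(rng.uniform(-2, 2), rng.uniform(0.5, 3), nx)
            y = rng.normal(rng.uniform(-2, 2), rng.uniform(0.5, 3), ny)
            t, _df, p = welch_t(x, y)
            ref = sps.ttest_ind(x, y, equal_var=False)
            assert t == pytest.approx(ref.statistic, abs=1e-10)
            assert p == pytest.approx(ref.pvalue, abs=1e-10)


class TestMinmaxNorm:
    @pytest.mark.parametrize(
        "x,expected",
        [
            ((0, 5, 10), (0, 0.5, 1)),
            ((3, 3, 3), (0, 0, 0)),
            ((1, 2, 4), (0, 1 / 3, 1)),
        ],
    )
    def test_examples(self, x, expected):
        assert minmax_norm(x) == pytest.approx(expected)

    def test_empty_rejected(self):
        with pytest.raises(StatError):
            minmax_norm([])

    def test_nonfinite_rejected(self):
        with pytest.raises(StatError):
            minmax_norm([1.0, np.inf])

    @given(
        st.lists(
            st.floats(min_value=-1e6, max_value=1e6, allow_nan=False),
            min_size=2,
            max_size=50,
        )
    )
    @settings(max_examples=100, deadline=None)
    def test_endpoint_property(self, xs):
        out = minmax_norm(xs)
        assert np.all(out >= 0) and np.all(out <= 1)
        if max(xs) > min(xs):
            assert out[int(np.argmin(xs))] == 0.0
            assert out[int(np.argmax(xs))] == 1.0
        else:
            assert np.all(out == 0)


class TestFeatureScores:
    def worked_example(self):
        return feature_scores_from_stats(
            ["gene1", "gene2", "gene3"], [0.01, 0.1, 0.5], [0.5, 2.0, 1.0]
        )

    def test_worked_example_values(self):
        t = self.worked_example()
        assert t["fs_pval"].tolist() == pytest.approx([2, 1, 0.301], abs=5e-4)
        assert t["fs_rank"].tolist() == pytest.approx([3, 6, 2])
        assert t["fs_norm"].tolist() == pytest.approx([0, 0.4114, 0], abs=5e-5)

    def test_p_of_one_scores_zero(self):
        t = feature_scores_from_stats(["a", "b"], [1.0, 0.5], [10.0, 0.1])
        row = t[t["gene"] == "a"].iloc[0]
        assert row["fs_pval"] == 0.0
        assert row["fs_norm"] == 0.0

    def test_promotion_of_large_effect(self):
        # the pval-top gene differs from the rank/norm-top gene when a
        # slightly less significant gene has a much larger effect size
        t = self.worked_example()
        assert select_top_k(t, "pval", 1) == ["gene1"]
        assert select_top_k(t, "rank", 1) == ["gene2"]
        assert select_top_k(t, "norm", 1) == ["gene2"]

    def test_p_clamped_before_log(self):
        t = feature_scores_from_stats(["a", "b"], [1e-320, 0.5], [1.0, 2.0])
        assert np.isfinite(t["fs_pval"]).all()
        assert t["fs_pval"].iloc[0] == pytest.approx(300.0)

    def test_norm_invariant_under_effect_rescaling(self):
        rng = np.random.default_rng(5)
        p = rng.uniform(1e-6, 1, 30)
        d = rng.normal(0, 2, 30)
        base = feature_scores_from_stats(range(30), p, d)
        scaled = feature_scores_from_stats(range(30), p, 7.5 * d)
        assert base["fs_norm"].to_numpy() == pytest.approx(
            scaled["fs_norm"].to_numpy()
        )

    def test_equal_effects_make_scores_agree(self):
        # with all |d| equal each score is a monotone function of p (norm
        # degenerates to zeros and falls back to the p tie-break)
        rng = np.random.default_rng(8)
        p = rng.uniform(1e-5, 1, 40)
        d = np.full(40, 1.3)
        t = feature_scores_from_stats([f"g{i}" for i in range(40)], p, d)
        for k in (1, 5, 20, 40):
            sets = {
                fs: frozenset(select_top_k(t, fs, k))
                for fs in ("pval", "rank", "norm")
            }
            assert sets["pval"] == sets["rank"] == sets["norm"]


class TestComputeFeatureTable:
    def test_matches_scalar_welch(self, strong_cohort, to_contrast):
        cohort, _ = strong_cohort
        table = compute_feature_table(cohort, to_contrast)
        mask = cohort.binary_response("TO")
        rng = np.random.default_rng(0)
        for i in rng.integers(0, cohort.expression.n_genes, 10):
            x = cohort.expression.values[i, mask]
            y = cohort.expression.values[i, ~mask]
            _t, _df, p = welch_t(x, y)
            assert table["p"].iloc[i] == pytest.approx(p, abs=1e-12)
            assert table["d"].iloc[i] == pytest.approx(
                x.mean() - y.mean(), abs=1e-12
            )

    def test_signed_effect_kept(self, strong_cohort, to_contrast):
        cohort, truth = strong_cohort
        table = compute_feature_table(cohort, to_contrast).set_index("gene")
        planted = table.loc[sorted(truth.to_genes)]
        assert (planted["d"] > 0).mean() > 0.95  # positive shift planted
        assert np.array_equal(planted["abs_d"], np.abs(planted["d"]))

    def test_planted_genes_recovered(self, strong_cohort, to_contrast):
        cohort, truth = strong_cohort
        table = compute_feature_table(cohort, to_contrast)
        top = set(select_top_k(table, "norm", 40))
        assert len(top & truth.to_genes) >= 0.8 * len(truth.to_genes)


class TestSelectTopK:
    def test_k_equals_g_is_permutation(self):
        t = feature_scores_from_stats(["a", "b", "c"], [0.2, 0.5, 0.01], [1, 2, 3])
        assert sorted(select_top_k(t, "rank", 3)) == ["a", "b", "c"]

    def test_k_out_of_range(self):
        t = feature_scores_from_stats(["a"], [0.5], [1.0])
        with pytest.raises(SelectionError):
            select_top_k(t, "pval", 2)
        with pytest.raises(SelectionError):
            select_top_k(t, "pval", 0)

    def test_unknown_fs_type(self):
        t = feature_scores_from_stats(["a"], [0.5], [1.0])
        with pytest.raises(SelectionError):
            select_top_k(t, "zscore", 1)

    def test_tie_break_by_p_then_gene(self):
        # equal fs_norm (all zero thanks to equal |d|), ties resolved by p
        # first and gene id second
        t = feature_scores_from_stats(
            ["gz", "ga", "gm"], [0.5, 0.1, 0.1], [1.0, 1.0, 1.0]
        )
        assert select_top_k(t, "norm", 3) == ["ga", "gm", "gz"]


def test_empty_contrast_group_rejected(tiny_expr):
    from crtpredict import CohortDataset, DworakLabels

    labels = DworakLabels(tiny_expr.sample_ids, ("MO", "MO", "MO", "MO"))
    cohort = CohortDataset(tiny_expr, labels)
    with pytest.raises(StatError):
        compute_feature_table(cohort, BinaryContrast("TO"))


def test_contrast_validation():
    with pytest.raises(StatError):
        BinaryContrast("MO")
    assert BinaryContrast("TO").contrast_name == "TO-vs-rest"
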