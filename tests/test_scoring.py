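"""Unit and property tests for baselines, ranks and the local/sample scores."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

from rankwarn import (ExpressionMatrix, compute_baseline, local_scores,
                      normalize_by_min, rank_expressions, sample_score,
                      score_series)

finite_floats = st.floats(-1e6, 1e6, allow_nan=False, allow_infinity=False)


def expr_vectors(min_size=2, max_size=60):
    return hnp.arrays(np.float64, st.integers(min_size, max_size),
                      elements=finite_floats)


class TestRankExpressions:
    @pytest.mark.parametrize("values, expected", [
        ([0.5, 2.0, 1.0], [1, 3, 2]),
        ([1.0, 1.0, 2.0], [1.5, 1.5, 3]),
        ([7.0, 7.0, 7.0, 7.0], [2.5, 2.5, 2.5, 2.5]),
    ])
    def test_fractional_ranks(self, values, expected):
        np.testing.assert_allclose(rank_expressions(values), expected)

    def test_rejects_nan_and_short_input(self):
        with pytest.raises(ValueError, match="NaN"):
            rank_expressions([1.0, np.nan])
        with pytest.raises(ValueError, match="at least 2"):
            rank_expressions([1.0])

    @settings(deadline=None)
    @given(expr_vectors())
    def test_rank_sum_is_n_n_plus_1_over_2(self, values):
        n = values.size
        assert rank_expressions(values).sum() == pytest.approx(n * (n + 1) / 2)


class TestComputeBaseline:
    def test_mean_and_tie_ranks(self, tiny_matrix):
        b = compute_baseline(tiny_matrix)
        np.testing.assert_allclose(b.expression, [2, 2, 3])
        np.testing.assert_allclose(b.rank, [1.5, 1.5, 3])
        assert b.n_normal == 2

    def test_single_sample_baseline_is_that_sample(self):
        m = ExpressionMatrix([[4.0], [1.0]], gene_ids=["a", "b"],
                             sample_ids=["n"])
        b = compute_baseline(m)
        np.testing.assert_allclose(b.expression, [4.0, 1.0])

    def test_identical_samples_mean_equals_any_column(self, rng):
        col = rng.normal(size=10)
        m = ExpressionMatrix(np.column_stack([col] * 3),
                             gene_ids=[f"g{i}" for i in range(10)],
                             sample_ids=["s1", "s2", "s3"])
        np.testing.assert_allclose(compute_baseline(m).expression, col)

    def test_nan_rejected_naming_gene(self):
        with pytest.raises(ValueError, match="gene_b"):
            ExpressionMatrix([[1.0, 2.0], [np.nan, 0.0]],
                             gene_ids=["gene_a", "gene_b"],
                             sample_ids=["s1", "s2"])


class TestLocalScores:
    def test_hand_computed_example(self, ladder_baseline):
        t = local_scores(np.array([3.0, 2.0, 1.0]), ladder_baseline)
        np.testing.assert_allclose(t.delta_expression, [2, 0, -2])
        np.testing.assert_allclose(t.delta_rank, [2, 0, -2])
        np.testing.assert_allclose(t.local_score, [4, 0, 4])

    def test_self_comparison_is_all_zero(self, ladder_baseline):
        t = local_scores(ladder_baseline.expression.copy(), ladder_baseline)
        assert (t.local_score == 0).all()
        assert (t.delta_rank == 0).all()

    def test_constant_shift_keeps_ranks(self, ladder_baseline):
        t = local_scores(ladder_baseline.expression + 7.5, ladder_baseline)
        np.testing.assert_array_equal(t.delta_rank, 0)
        np.testing.assert_allclose(t.delta_expression, 7.5)
        np.testing.assert_array_equal(t.local_score, 0)

    def test_gene_universe_intersection_warns(self, ladder_baseline):
        sample = pd.Series({"a": 1.0, "b": 5.0, "zzz": 2.0})
        with pytest.warns(UserWarning, match="intersect"):
            t = local_scores(sample, ladder_baseline)
        assert t.gene_ids == ("a", "b")

    def test_disjoint_universes_error(self, ladder_baseline):
        with pytest.raises(ValueError, match="share only"):
            local_scores(pd.Series({"x": 1.0, "y": 2.0}), ladder_baseline)


class TestSampleScore:
    def test_top_two_of_three(self, ladder_baseline):
        t = local_scores(np.array([3.0, 2.0, 1.0]), ladder_baseline)
        assert sample_score(t, 2) == pytest.approx((4 + 4) / 2 / 3)

    def test_all_zero_scores_give_zero(self, ladder_baseline):
        t = local_scores(ladder_baseline.expression.copy(), ladder_baseline)
        assert sample_score(t, 3) == 0.0

    def test_m_equal_n_is_mean_over_n(self, rng):
        base = compute_baseline(ExpressionMatrix(
            rng.normal(size=(30, 4)), gene_ids=[f"g{i}" for i in range(30)],
            sample_ids=list("wxyz")))
        t = local_scores(rng.normal(size=30), base)
        assert sample_score(t, 30) == pytest.approx(t.local_score.mean() / 30)

    def test_m_larger_than_n_raises(self, ladder_baseline):
        t = local_scores(np.array([3.0, 2.0, 1.0]), ladder_baseline)
        with pytest.raises(ValueError, match="exceeds"):
            sample_score(t, 4)

    def test_absolute_option_uses_magnitudes(self, rng):
        base = compute_baseline(ExpressionMatrix(
            np.arange(20, dtype=float).reshape(-1, 1),
            gene_ids=[f"g{i:02d}" for i in range(20)], sample_ids=["n"]))
        sample = base.expression.copy()
        sample[0] += 30.0   # up-shift: positive product
        sample[19] -= 30.0  # down-shift: positive product
        sample[10] += 2.05  # small discordant wiggle
        t = local_scores(sample, base)
        # the two coordinated shifts dominate under either criterion
        assert sample_score(t, 2, use_absolute=True) == sample_score(t, 2)
        # with m covering everything, absolute selection includes the
        # negative product that signed selection also includes; sums match
        assert sample_score(t, 20, use_absolute=True) == sample_score(t, 20)


class TestScoreSeries:
    def test_ranking_scores_subtract_first_point(self, rng):
        genes = [f"g{i}" for i in range(40)]
        base = compute_baseline(ExpressionMatrix(
            rng.normal(size=(40, 3)), gene_ids=genes,
            sample_ids=["n1", "n2", "n3"]))
        course = ExpressionMatrix(rng.normal(size=(40, 5)), gene_ids=genes,
                                  sample_ids=list("abcde"))
        s = score_series(course, base, m=10)
        assert s.ranking_scores[0] == 0.0
        np.testing.assert_allclose(s.ranking_scores,
                                   s.raw_scores - s.raw_scores[0])

    def test_single_time_point_gives_zero(self, ladder_baseline):
        course = ExpressionMatrix([[9.0], [1.0], [5.0]],
                                  gene_ids=["a", "b", "c"], sample_ids=["t0"])
        s = score_series(course, ladder_baseline, m=2)
        np.testing.assert_array_equal(s.ranking_scores, [0.0])

    def test_course_equal_to_baseline_gives_zero_everywhere(self, ladder_baseline):
        course = ExpressionMatrix(
            np.tile(ladder_baseline.expression[:, None], 4),
            gene_ids=["a", "b", "c"], sample_ids=["t0", "t1", "t2", "t3"])
        s = score_series(course, ladder_baseline, m=3)
        np.testing.assert_array_equal(s.raw_scores, 0.0)

    def test_duplicate_time_labels_rejected(self, ladder_baseline, rng):
        course = ExpressionMatrix(rng.normal(size=(3, 2)),
                                  gene_ids=["a", "b", "c"],
                                  sample_ids=["t0", "t1"])
        with pytest.raises(ValueError, match="duplicate time labels"):
            score_series(course, ladder_baseline, m=2,
                         time_labels=["x", "x"])


class TestNormalizeByMin:
    @pytest.mark.parametrize("values, expected", [
        ([2, 4, 8], [1, 2, 4]),
        ([5], [1]),
        ([1, 1, 1], [1, 1, 1]),
    ])
    def test_examples(self, values, expected):
        np.testing.assert_allclose(normalize_by_min(values), expected)

    def test_nonpositive_minimum_rejected(self):
        with pytest.raises(ValueError, match="strictly positive"):
            normalize_by_min([2.0, 0.0, 3.0])
        with pytest.raises(ValueError, match="empty"):
            normalize_by_min([])


class TestInvariances:
    """Algebraic invariances of the scoring statistic."""

    @settings(deadline=None, max_examples=40)
    @given(st.integers(5, 40), st.integers(0, 10_000),
           st.floats(-50, 50, allow_nan=False))
    def test_shift_invariance_of_delta_rank(self, n, seed, shift):
        r = np.random.default_rng(seed)
        genes = [f"g{i:03d}" for i in range(n)]
        base = compute_baseline(ExpressionMatrix(
            r.normal(size=(n, 3)), gene_ids=genes,
            sample_ids=["a", "b", "c"]))
        sample = r.normal(size=n)
        t0 = local_scores(sample, base)
        t1 = local_scores(sample + shift, base)
        np.testing.assert_array_equal(t0.delta_rank, t1.delta_rank)

    @settings(deadline=None, max_examples=40)
    @given(st.integers(5, 40), st.integers(0, 10_000),
           st.floats(0.01, 100, allow_nan=False))
    def test_positive_scaling_scales_score_linearly(self, n, seed, c):
        r = np.random.default_rng(seed)
        genes = [f"g{i:03d}" for i in range(n)]
        normals = r.normal(size=(n, 3))
        sample = r.normal(size=n)
        m = max(1, n // 3)

        def score(mat, vec):
            base = compute_baseline(ExpressionMatrix(
                mat, gene_ids=genes, sample_ids=["a", "b", "c"]))
            return sample_score(local_scores(vec, base), m)

        s1 = score(normals, sample)
        s2 = score(c * normals, c * sample)
        assert s2 == pytest.approx(c * s1, rel=1e-9, abs=1e-12)

    @settings(deadline=None, max_examples=40)
    @given(st.integers(5, 40), st.integers(0, 10_000))
    def test_gene_permutation_invariance(self, n, seed):
        r = np.random.default_rng(seed)
        genes = [f"g{i:03d}" for i in range(n)]
        normals = r.normal(size=(n, 2))
        sample = r.normal(size=n)
        perm = r.permutation(n)
        m = max(1, n // 4)

        def score(mat, vec, ids):
            base = compute_baseline(ExpressionMatrix(
                mat, gene_ids=ids, sample_ids=["a", "b"]))
            return sample_score(local_scores(vec, base), m)

        s1 = score(normals, sample, genes)
        s2 = score(normals[perm], sample[perm], [genes[i] for i in perm])
        assert s2 == pytest.approx(s1, rel=1e-12, abs=1e-15)
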