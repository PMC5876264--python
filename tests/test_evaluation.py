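import math

import numpy as np
import pytest
from hypothesis import assume, given, settings
from hypothesis import strategies as st

from hamscore.errors import ValidationError, ZeroVarianceError
from hamscore.evaluation import (
    cohens_d,
    correlate,
    dichotomize_and_compare,
    evaluate,
    ks_normality,
    variance_explained_pct,
)


# --- naive textbook-formula oracles, independent of scipy ----------------


def naive_pearson(x, y):
    n = len(x)
    mx, my = sum(x) / n, sum(y) / n
    cov = sum((a - mx) * (b - my) for a, b in zip(x, y))
    vx = sum((a - mx) ** 2 for a in x)
    vy = sum((b - my) ** 2 for b in y)
    return cov / math.sqrt(vx * vy)


def midranks(values):
    srt = sorted(values)
    return [
        (srt.index(v) + 1 + (len(srt) - srt[::-1].index(v) - 1) + 1) / 2 for v in values
    ]


def naive_spearman(x, y):
    return naive_pearson(midranks(x), midranks(y))


def naive_cohens_d(a, b):
    na, nb = len(a), len(b)
    ma, mb = sum(a) / na, sum(b) / nb
    va = sum((x - ma) ** 2 for x in a) / (na - 1)
    vb = sum((x - mb) ** 2 for x in b) / (nb - 1)
    sp = math.sqrt(((na - 1) * va + (nb - 1) * vb) / (na + nb - 2))
    return (ma - mb) / sp


class TestCorrelate:
    def test_perfect_linear(self):
        res = correlate([1, 2, 3], [10, 20, 30])
        assert res.pearson_r == pytest.approx(1.0)
        assert res.variance_explained_pct == pytest.approx(100.0)

    def test_variance_explained_approximately_four_percent(self):
        # the printed coefficient of 0.205 explains ~4% of the variance
        assert variance_explained_pct(0.205) == pytest.approx(4.2025)
        assert round(variance_explained_pct(0.205)) == 4

    def test_spearman_is_pearson_of_midranks(self):
        scores, rts = [1, 1, 2, 2], [4, 3, 2, 1]
        res = correlate(scores, rts)
        assert res.spearman_rho == pytest.approx(naive_spearman(scores, rts))

    def test_zero_variance_is_defined_error(self):
        with pytest.raises(ZeroVarianceError):
            correlate([5, 5, 5], [1, 2, 3])
        with pytest.raises(ZeroVarianceError):
            correlate([1, 2, 3], [7, 7, 7])

    def test_too_short_rejected(self):
        with pytest.raises(ValidationError):
            correlate([1, 2], [3, 4])

    def test_out_of_range_coefficient_rejected(self):
        with pytest.raises(ValidationError):
            variance_explained_pct(1.5)

    @settings(max_examples=100, deadline=None)
    @given(
        data=st.lists(
            st.tuples(st.integers(0, 19), st.integers(1, 80)), min_size=3, max_size=8
        ),
        scale=st.floats(0.1, 10, allow_nan=False),
        shift=st.floats(-50, 50, allow_nan=False),
    )
    def test_affine_and_monotone_invariance(self, data, scale, shift):
        score = [s for s, _ in data]
        rts = [float(r) for _, r in data]
        assume(len(set(score)) > 1 and len(set(rts)) > 1)
        base = correlate(score, rts)
        affine = correlate(score, [scale * r + shift for r in rts])
        assert affine.pearson_r == pytest.approx(base.pearson_r, abs=1e-9)
        cubed = correlate(score, [r**3 for r in rts])  # strictly monotone
        assert cubed.spearman_rho == pytest.approx(base.spearman_rho, abs=1e-9)


class TestDichotomize:
    @pytest.mark.filterwarnings("ignore::RuntimeWarning")
    def test_degenerate_zero_variance_groups(self):
        cmp = dichotomize_and_compare([9, 9, 10, 10], [20, 20, 30, 30])
        assert cmp.mean_difference == pytest.approx(10.0)
        assert cmp.effect_size_d is None  # not infinity, a defined absence
        assert any("pooled SD" in n for n in cmp.notes)

    def test_equal_means_give_zero_d(self):
        cmp = dichotomize_and_compare([1, 1, 20, 20], [5.0, 7.0, 5.0, 7.0])
        assert cmp.mean_difference == pytest.approx(0.0)
        assert cmp.effect_size_d == pytest.approx(0.0)

    def test_empty_group_keeps_partition(self):
        cmp = dichotomize_and_compare([4, 5, 6], [10, 20, 30], threshold=10)
        assert cmp.at_or_above is None
        assert cmp.below.n == 3
        assert cmp.mean_difference is None and cmp.effect_size_d is None
        assert any("empty" in n for n in cmp.notes)

    def test_direction_of_difference(self):
        cmp = dichotomize_and_compare(
            [4, 5, 6, 11, 12, 13], [10.0, 12.0, 11.0, 30.0, 31.0, 29.0]
        )
        assert cmp.mean_difference > 0
        assert cmp.effect_size_d == pytest.approx(
            naive_cohens_d([30.0, 31.0, 29.0], [10.0, 12.0, 11.0])
        )

    @settings(max_examples=100, deadline=None)
    @given(
        scores=st.lists(st.integers(0, 19), min_size=1, max_size=30),
        threshold=st.integers(1, 20),
    )
    def test_partition_exhaustive_and_exclusive(self, scores, threshold):
        rts = [float(i + 1) for i in range(len(scores))]
        cmp = dichotomize_and_compare(scores, rts, threshold)
        n_below = cmp.below.n if cmp.below else 0
        n_above = cmp.at_or_above.n if cmp.at_or_above else 0
        assert n_below + n_above == len(scores)
        assert n_below == sum(1 for s in scores if s < threshold)


class TestKSNormality:
    def test_normal_sample_passes(self):
        rng = np.random.default_rng(1)
        res = ks_normality(rng.normal(size=1000))
        assert res.pvalue > 0.05

    def test_exponential_sample_fails(self):
        rng = np.random.default_rng(2)
        res = ks_normality(rng.exponential(size=1000))
        assert res.pvalue < 0.05

    @settings(max_examples=50, deadline=None)
    @given(
        values=st.lists(st.floats(-1e3, 1e3, allow_nan=False), min_size=5, max_size=50)
    )
    def test_statistic_bounded(self, values):
        assume(len(set(values)) > 1)
        res = ks_normality(values)
        assert 0.0 <= res.statistic <= 1.0

    def test_constant_vector_rejected(self):
        with pytest.raises(ZeroVarianceError):
            ks_normality([3.0] * 10)

    def test_too_short_rejected(self):
        with pytest.raises(ValidationError):
            ks_normality([1.0, 2.0, 3.0])


class TestOracleEquivalence:
    """All statistics match naive textbook formulas on short vectors."""

    @settings(max_examples=150, deadline=None)
    @given(
        data=st.lists(
            st.tuples(st.integers(0, 19), st.integers(1, 66)), min_size=3, max_size=8
        )
    )
    def test_correlations_match_naive(self, data):
        score = [float(s) for s, _ in data]
        rts = [float(r) for _, r in data]
        assume(len(set(score)) > 1 and len(set(rts)) > 1)
        res = correlate(score, rts)
        assert res.pearson_r == pytest.approx(naive_pearson(score, rts), abs=1e-9)
        assert res.spearman_rho == pytest.approx(naive_spearman(score, rts), abs=1e-9)
        assert res.variance_explained_pct == pytest.approx(
            100 * naive_pearson(score, rts) ** 2, abs=1e-7
        )

    @settings(max_examples=150, deadline=None)
    @given(
        a=st.lists(st.floats(0, 100, allow_nan=False), min_size=2, max_size=8),
        b=st.lists(st.floats(0, 100, allow_nan=False), min_size=2, max_size=8),
    )
    def test_cohens_d_matches_naive(self, a, b):
        assume(len(set(a)) > 1 or len(set(b)) > 1)
        assume(np.std(a + b) > 1e-6)  # avoid catastrophic-cancellation regimes
        assert cohens_d(a, b) == pytest.approx(naive_cohens_d(a, b), rel=1e-9, abs=1e-9)


class TestEvaluate:
    def test_bundles_all_pieces(self):
        rng = np.random.default_rng(5)
        score = rng.integers(4, 13, size=60)
        rts = 12 + 1.3 * score + rng.normal(0, 8, size=60)
        res = evaluate(score, rts, threshold=10)
        d = res.to_dict()
        assert {"pearson_r", "spearman_rho", "variance_explained_pct"} <= set(d)
        assert set(d["ks_normality"]) == {"total_score", "rts_days"}
        assert d["group_below"]["n"] + d["group_at_or_above"]["n"] == 60
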