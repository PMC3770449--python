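"""Aggregation, empirical threshold, and selection rule."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from intomics.data import StatMatrix, ValidationError
from intomics.decision import (
    aggregate_linear,
    aggregate_quadratic,
    null_aggregate,
    select,
    threshold,
)
from intomics.permutation import NullDistribution, build_null
from intomics.stats import TestSpec, compute_stat_matrix
from tests.conftest import make_platform


def make_null(pooled_raw, sigma_hat=None, pooled=None):
    pooled_raw = np.asarray(pooled_raw, float)
    pooled = pooled_raw if pooled is None else np.asarray(pooled, float)
    sigma = (
        pooled_raw.std(axis=0, ddof=1) if sigma_hat is None
        else np.asarray(sigma_hat, float)
    )
    return NullDistribution(
        pooled=pooled,
        pooled_raw=pooled_raw,
        sigma_hat=sigma,
        cov_hat=np.atleast_2d(np.cov(pooled_raw, rowvar=False, ddof=1)),
        B=1,
        seed=None,
        scale_basis="raw",
        platform_ids=np.array(
            [f"p{q}" for q in range(pooled_raw.shape[1])], dtype=object
        ),
    )


def make_stats(adjusted, raw=None):
    adjusted = np.atleast_2d(np.asarray(adjusted, float))
    raw = adjusted if raw is None else np.atleast_2d(np.asarray(raw, float))
    n, q = adjusted.shape
    return StatMatrix(
        stats=adjusted,
        raw=raw,
        platform_ids=np.array([f"p{i}" for i in range(q)], dtype=object),
        biomarker_ids=np.array([f"b{i}" for i in range(n)], dtype=object),
    )


class TestLinearAggregation:
    def test_unit_weights(self):
        null = make_null(np.zeros((3, 2)), sigma_hat=[1.0, 1.0])
        assert aggregate_linear(make_stats([[2.0, 3.0]]), null)[0] == 5.0

    def test_inverse_sd_weights(self):
        null = make_null(np.zeros((3, 2)), sigma_hat=[2.0, 0.5])
        assert aggregate_linear(make_stats([[2.0, 3.0]]), null)[0] == 7.0

    def test_dimension_mismatch(self):
        null = make_null(np.zeros((3, 2)), sigma_hat=[1.0, 1.0])
        with pytest.raises(ValidationError):
            aggregate_linear(make_stats([[1.0, 2.0, 3.0]]), null)

    def test_monotone_in_each_statistic(self):
        null = make_null(np.zeros((3, 2)), sigma_hat=[1.3, 0.7])
        base = aggregate_linear(make_stats([[1.0, 1.0]]), null)[0]
        for q in range(2):
            row = np.ones((1, 2))
            row[0, q] += 0.5
            assert aggregate_linear(make_stats(row), null)[0] > base

    def test_platform_rescaling_leaves_selection_invariant(self, rng):
        """Multiplying one platform's data by c > 0 (mean_diff statistic)
        rescales its statistics and sigma together, so the selected set
        is unchanged."""
        vals1 = rng.standard_normal((50, 10))
        vals2 = rng.standard_normal((50, 10)) + np.linspace(0, 1, 50)[:, None]
        specs = [TestSpec("mean_diff", "right")] * 2

        def run(c):
            p = [
                make_platform(vals1, platform_id="a"),
                make_platform(vals2 * c, platform_id="b"),
            ]
            sm = compute_stat_matrix(p, specs)
            null = build_null(p, specs, B=40, seed=5)
            return select(sm, null, alpha=0.1)

        r1, r10 = run(1.0), run(10.0)
        np.testing.assert_array_equal(r1.selected_mask, r10.selected_mask)


class TestQuadraticAggregation:
    def test_identity_covariance(self):
        null = make_null(np.eye(2).repeat(50, 0))  # cov close to diag
        null.cov_hat = np.eye(2)
        out = aggregate_quadratic(make_stats([[3.0, 4.0]]), null)
        assert out[0] == pytest.approx(25.0)

    def test_zero_vector(self):
        null = make_null(np.random.default_rng(0).normal(size=(50, 2)))
        assert aggregate_quadratic(make_stats([[0.0, 0.0]]), null)[0] == 0.0

    def test_affine_invariance(self, rng):
        """Mahalanobis form is invariant under any invertible linear map
        applied jointly to the observed and null vectors."""
        pooled = rng.standard_normal((400, 2)) @ np.array([[1.0, 0.3], [0.0, 0.8]])
        V = rng.standard_normal((20, 2))
        A = np.array([[2.0, -1.0], [0.5, 1.5]])
        t1 = aggregate_quadratic(make_stats(V), make_null(pooled))
        t2 = aggregate_quadratic(make_stats(V @ A.T), make_null(pooled @ A.T))
        np.testing.assert_allclose(t1, t2, atol=1e-8)

    def test_singular_covariance_error(self):
        pooled = np.random.default_rng(1).normal(size=(100, 1)) @ np.ones((1, 2))
        null = make_null(pooled)
        with pytest.raises(ValidationError, match="singular"):
            aggregate_quadratic(make_stats([[1.0, 1.0]]), null)


class TestThreshold:
    def test_percentile_order_statistic(self):
        assert threshold(np.arange(1, 101), 0.05) == 95.0

    def test_alpha_one_gives_minimum(self):
        assert threshold(np.array([4.0, 2.0, 9.0]), 1.0) == 2.0

    @pytest.mark.parametrize("alpha", [0.0, -0.1, 1.5])
    def test_invalid_alpha(self, alpha):
        with pytest.raises(ValidationError):
            threshold(np.arange(10), alpha)

    @given(
        vals=st.lists(st.floats(-100, 100, allow_nan=False), min_size=1,
                      max_size=60),
        a1=st.floats(0.01, 1.0),
        a2=st.floats(0.01, 1.0),
    )
    @settings(derandomize=True, max_examples=100, deadline=None)
    def test_monotone_nonincreasing_in_alpha(self, vals, a1, a2):
        lo, hi = sorted((a1, a2))
        assert threshold(vals, lo) >= threshold(vals, hi)

    def test_threshold_is_attained_value(self):
        vals = np.random.default_rng(2).normal(size=101)
        c = threshold(vals, 0.25)
        assert c in vals


class TestSelect:
    def test_strict_inequality_at_boundary(self):
        null = make_null(np.arange(1.0, 101.0)[:, None], sigma_hat=[1.0])
        # C_0.05 = 95; t_agg (95, 96): only the second exceeds strictly
        res = select(make_stats([[95.0], [96.0]]), null, alpha=0.05)
        assert res.C_alpha == 95.0
        np.testing.assert_array_equal(res.selected_mask, [False, True])
        assert list(res.selected) == ["b1"]

    def test_decision_line_for_two_platforms(self, two_noise_platforms):
        specs = [TestSpec("student_t", "right")] * 2
        sm = compute_stat_matrix(two_noise_platforms, specs)
        null = build_null(two_noise_platforms, specs, B=20, seed=9)
        res = select(sm, null, alpha=0.1)
        w1, w2, c = res.decision_line
        assert w1 == pytest.approx(1 / null.sigma_hat[0])
        assert w2 == pytest.approx(1 / null.sigma_hat[1])
        assert c == res.C_alpha
        # selection equals the half-plane rule
        np.testing.assert_array_equal(
            res.selected_mask, sm.stats @ [w1, w2] > c
        )

    def test_quadratic_select_runs(self, two_noise_platforms):
        specs = [TestSpec("student_t", "two")] * 2
        sm = compute_stat_matrix(two_noise_platforms, specs)
        null = build_null(two_noise_platforms, specs, B=20, seed=9)
        res = select(sm, null, alpha=0.1, method="quadratic")
        assert (res.t_agg >= 0).all()
        assert res.decision_line is None

    def test_null_aggregate_sizes(self, two_noise_platforms):
        specs = [TestSpec("student_t", "two")] * 2
        null = build_null(two_noise_platforms, specs, B=13, seed=4)
        for method in ("linear", "quadratic"):
            agg = null_aggregate(null, method)
            assert agg.shape == (13 * 20,)
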