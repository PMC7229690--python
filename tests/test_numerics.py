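"""Rectangle probabilities, Gaussian expectations, and the root finder."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.special import ndtr
from scipy.stats import multivariate_normal

from ratdecide import (
    RectangleRegion,
    expectation_over_gaussian,
    monotone_root,
    mvn_rectangle_probability,
)
from ratdecide.numerics import rectangle_probabilities


def exchangeable_cov(m, rho, var=1.0):
    cov = np.full((m, m), rho)
    np.fill_diagonal(cov, var)
    return cov


class TestRectangleProbability:
    def test_univariate_half_line(self):
        p = mvn_rectangle_probability([0.0], [[1.0]], RectangleRegion((0.0,), (np.inf,)))
        assert p == pytest.approx(0.5, abs=1e-12)

    def test_independent_orthant(self):
        p = mvn_rectangle_probability([0, 0], np.eye(2), RectangleRegion((0, 0), (np.inf, np.inf)))
        assert p == pytest.approx(0.25, abs=1e-9)

    def test_correlated_orthant_closed_form(self):
        # P(X>0, Y>0) = 1/4 + arcsin(rho)/(2*pi); equals 1/3 at rho = 0.5
        p = mvn_rectangle_probability([0, 0], exchangeable_cov(2, 0.5),
                                      RectangleRegion((0, 0), (np.inf, np.inf)))
        assert p == pytest.approx(1.0 / 3.0, abs=1e-6)

    def test_full_space_is_one(self):
        cov = exchangeable_cov(5, 0.7, var=1.3)
        p = mvn_rectangle_probability(np.zeros(5), cov,
                                      RectangleRegion((-np.inf,) * 5, (np.inf,) * 5))
        assert p == pytest.approx(1.0, abs=1e-6)

    def test_monotone_under_region_enlargement(self):
        cov = exchangeable_cov(3, 0.4)
        small = mvn_rectangle_probability(np.zeros(3), cov,
                                          RectangleRegion((-1, -1, -1), (1, 1, 1)))
        big = mvn_rectangle_probability(np.zeros(3), cov,
                                        RectangleRegion((-2, -1, -1), (1, 2, 1)))
        assert small <= big <= 1.0

    def test_permutation_invariance(self):
        cov = np.array([[1.0, 0.3, 0.6], [0.3, 1.5, 0.2], [0.6, 0.2, 2.0]])
        lo, hi = np.array([-0.5, 0.0, -np.inf]), np.array([1.0, 2.0, 0.7])
        perm = [2, 0, 1]
        p1 = mvn_rectangle_probability(np.zeros(3), cov, RectangleRegion(tuple(lo), tuple(hi)))
        p2 = mvn_rectangle_probability(
            np.zeros(3), cov[np.ix_(perm, perm)],
            RectangleRegion(tuple(lo[perm]), tuple(hi[perm])))
        assert p1 == pytest.approx(p2, abs=2e-6)

    @pytest.mark.parametrize("m", [2, 4, 7])
    def test_agrees_with_independent_qmc_oracle(self, m):
        """Cross-check against scipy's independently implemented MVN CDF."""
        rng = np.random.default_rng(m)
        cov = exchangeable_cov(m, 0.6, var=1.8)
        lo = rng.normal(size=m) - 1.0
        hi = lo + rng.uniform(1.0, 3.0, size=m)
        mine = mvn_rectangle_probability(np.zeros(m), cov, RectangleRegion(tuple(lo), tuple(hi)))
        ref = np.mean([multivariate_normal.cdf(hi, mean=np.zeros(m), cov=cov, lower_limit=lo)
                       for _ in range(5)])
        assert mine == pytest.approx(ref, abs=5e-5)  # scipy's own estimate is randomized

    def test_mean_shift(self):
        p = mvn_rectangle_probability([1.0], [[1.0]], RectangleRegion((0.0,), (np.inf,)))
        assert p == pytest.approx(ndtr(1.0), abs=1e-12)

    def test_batched_matches_scalar(self):
        cov = exchangeable_cov(3, 0.5)
        lo = np.array([[-np.inf, 0.0, -1.0], [0.0, -np.inf, -2.0]])
        hi = np.array([[0.5, np.inf, 1.0], [2.0, 0.0, np.inf]])
        batch = rectangle_probabilities(lo, hi, cov)
        for i in range(2):
            single = mvn_rectangle_probability(
                np.zeros(3), cov, RectangleRegion(tuple(lo[i]), tuple(hi[i])))
            assert batch[i] == pytest.approx(single, abs=1e-12)

    def test_reflection_symmetry_exact(self):
        """Antithetic point set makes mirrored boxes evaluate identically."""
        cov = exchangeable_cov(4, 0.8, var=2.0)
        lo = np.array([0.3, -np.inf, -1.0, 0.0])
        hi = np.array([np.inf, -0.2, 2.0, np.inf])
        p = mvn_rectangle_probability(np.zeros(4), cov, RectangleRegion(tuple(lo), tuple(hi)))
        q = mvn_rectangle_probability(np.zeros(4), cov, RectangleRegion(tuple(-hi), tuple(-lo)))
        assert p == pytest.approx(q, abs=1e-14)

    def test_errors(self):
        with pytest.raises(ValueError):
            RectangleRegion((0.0, 0.0), (1.0, -1.0))  # lower >= upper
        with pytest.raises(ValueError, match="dimension mismatch"):
            mvn_rectangle_probability([0, 0], np.eye(3), RectangleRegion((0, 0), (1, 1)))
        with pytest.raises(ValueError, match="PSD"):
            mvn_rectangle_probability([0, 0], [[1, 2], [2, 1]], RectangleRegion((0, 0), (1, 1)))

    def test_rank_deficient_covariance_supported(self):
        # identical preferences: perfectly correlated coordinates
        cov = np.ones((2, 2))
        p = mvn_rectangle_probability([0, 0], cov, RectangleRegion((0, -np.inf), (np.inf, 0)))
        assert p == pytest.approx(0.0, abs=1e-9)


class TestExpectationOverGaussian:
    def test_identity_integrand_returns_mean(self):
        assert expectation_over_gaussian(lambda u: u, 0.3, 1.0) == pytest.approx(0.3, abs=1e-9)

    def test_square_integrand_returns_second_moment(self):
        assert expectation_over_gaussian(lambda u: u**2, 0.0, 2.0) == pytest.approx(4.0, rel=1e-9)

    def test_probit_integrand_symmetry(self):
        assert expectation_over_gaussian(ndtr, 0.0, 1.0) == pytest.approx(0.5, abs=1e-9)

    def test_nonfinite_integrand_rejected(self):
        with pytest.raises(ValueError, match="non-finite"):
            expectation_over_gaussian(lambda u: np.where(u > 0, np.inf, 0.0), 0.0, 1.0)

    @given(mean=st.floats(-3, 3), sd=st.floats(0.1, 3))
    @settings(max_examples=25, deadline=None)
    def test_affine_integrand_exact(self, mean, sd):
        got = expectation_over_gaussian(lambda u: 2.0 * u - 1.0, mean, sd)
        assert got == pytest.approx(2.0 * mean - 1.0, abs=1e-8)


class TestMonotoneRoot:
    def test_linear(self):
        assert monotone_root(lambda u: u - 1.0, tol=1e-8) == pytest.approx(1.0, abs=1e-8)

    def test_probit_shifted(self):
        assert monotone_root(lambda u: ndtr(u) - 0.5) == pytest.approx(0.0, abs=1e-8)

    def test_root_outside_initial_bracket(self):
        assert monotone_root(lambda u: u - 7.3) == pytest.approx(7.3, abs=1e-8)

    def test_degenerate_input_fails_loudly(self):
        with pytest.raises(RuntimeError, match="no sign change"):
            monotone_root(lambda u: np.exp(u))  # always positive
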