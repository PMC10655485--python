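"""Log-density building blocks against independent oracles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import dirichlet as sp_dirichlet
from scipy.stats import nbinom, norm

from dgd.distributions import (
    gmm_log_density,
    gmm_param_log_prior,
    gmm_responsibilities,
    nb_log_pmf,
    nb_log_pmf_grad,
    softball_log_density,
    softball_log_normalizer,
)


class TestNBLogPmf:
    def test_closed_form_at_zero(self):
        # k=0: pmf = (r/(r+m))^r
        assert nb_log_pmf(0, 2.0, 2.0) == pytest.approx(np.log(0.25), abs=1e-12)

    def test_geometric_special_case(self):
        # r=1 reduces to a geometric distribution
        expected = np.log((10 / 11) ** 5 * (1 / 11))
        assert nb_log_pmf(5, 10.0, 1.0) == pytest.approx(expected, abs=1e-12)

    @pytest.mark.parametrize("k,m,r", [
        (37, 50.0, 2.0),
        (0, 1.0, 0.5),
        (123, 7.3, 11.0),
        (10_000_000, 1e6, 3.0),
    ])
    def test_matches_scipy_oracle(self, k, m, r):
        # scipy parameterization: n=r, p=r/(r+m)
        expected = nbinom.logpmf(k, r, r / (r + m))
        # 1e-9 leaves room for float accumulation in the k*log(m/(r+m))
        # term at k ~ 1e7; small-k cases agree to ~1e-13
        assert nb_log_pmf(k, m, r) == pytest.approx(expected, abs=1e-9)
        assert np.isfinite(nb_log_pmf(k, m, r))

    @pytest.mark.parametrize("m", [1.0, 50.0, 1e3])
    @pytest.mark.parametrize("r", [0.5, 2.0, 20.0])
    def test_normalization(self, m, r):
        # exponentiated pmf sums to 1 over a range holding >=1-1e-9 of mass
        upper = int(nbinom.ppf(1 - 1e-10, r, r / (r + m))) + 10
        total = np.exp(nb_log_pmf(np.arange(upper + 1), m, r)).sum()
        assert total == pytest.approx(1.0, abs=1e-8)

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            nb_log_pmf(1, -1.0, 2.0)
        with pytest.raises(ValueError):
            nb_log_pmf(1, 2.0, 0.0)
        with pytest.raises(ValueError):
            nb_log_pmf(1.5, 2.0, 2.0)
        with pytest.raises(ValueError):
            nb_log_pmf(-1, 2.0, 2.0)

    def test_gradients_match_finite_differences(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            k = rng.integers(0, 200)
            m = rng.uniform(0.5, 100)
            r = rng.uniform(0.5, 30)
            dm, dr = nb_log_pmf_grad(k, m, r)
            eps = 1e-6
            dm_num = (nb_log_pmf(k, m + eps, r) - nb_log_pmf(k, m - eps, r)) / (2 * eps)
            dr_num = (nb_log_pmf(k, m, r + eps) - nb_log_pmf(k, m, r - eps)) / (2 * eps)
            assert dm == pytest.approx(dm_num, rel=1e-5, abs=1e-7)
            assert dr == pytest.approx(dr_num, rel=1e-5, abs=1e-7)


class TestSoftball:
    def test_center_beats_boundary(self):
        z0 = np.zeros(5)
        zb = np.r_[7.0, np.zeros(4)]
        assert softball_log_density(z0, 7.0, 10.0) > softball_log_density(zb, 7.0, 10.0)

    def test_mollifier_at_boundary_is_log_half(self):
        # at ||z|| = spread the sigmoid argument is 0: mollifier = -log 2
        z = np.r_[7.0, np.zeros(3)]
        expected = softball_log_normalizer(4, 7.0) - np.log(2.0)
        assert softball_log_density(z, 7.0, 10.0) == pytest.approx(expected, abs=1e-12)

    def test_value_outside_ball_matches_formula(self):
        spread, sharp = 3.0, 10.0
        z = np.r_[2 * spread, np.zeros(2)]
        expected = softball_log_normalizer(3, spread) - np.logaddexp(
            0.0, sharp * (2 * spread / spread - 1.0)
        )
        assert softball_log_density(z, spread, sharp) == pytest.approx(expected, abs=1e-12)

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=25, deadline=None)
    def test_rotation_invariance(self, seed):
        rng = np.random.default_rng(seed)
        z = rng.normal(size=6)
        q, _ = np.linalg.qr(rng.normal(size=(6, 6)))
        a = softball_log_density(z, 4.0, 8.0)
        b = softball_log_density(q @ z, 4.0, 8.0)
        assert a == pytest.approx(b, abs=1e-9)

    def test_monotone_in_radius(self):
        radii = np.linspace(0, 20, 50)
        vals = [softball_log_density(np.r_[r, np.zeros(2)], 7.0, 10.0) for r in radii]
        assert all(a >= b - 1e-12 for a, b in zip(vals, vals[1:]))


class TestGMMLogDensity:
    def test_standard_normal_mode(self):
        d = 4
        val = gmm_log_density(np.zeros(d), np.zeros((1, d)), np.zeros((1, d)), np.zeros(1))
        assert val == pytest.approx(-(d / 2) * np.log(2 * np.pi), abs=1e-12)

    def test_well_separated_equal_mixture(self):
        d = 3
        means = np.stack([np.zeros(d), np.full(d, 40.0)])
        val = gmm_log_density(np.zeros(d), means, np.zeros((2, d)),
                              np.log(np.full(2, 0.5)))
        expected = np.log(0.5) - (d / 2) * np.log(2 * np.pi)
        assert val == pytest.approx(expected, abs=1e-9)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_naive_sum_oracle(self, seed):
        rng = np.random.default_rng(seed)
        c, d = rng.integers(1, 6), rng.integers(1, 9)
        means = rng.normal(size=(c, d))
        beta = rng.normal(size=(c, d))
        w = rng.dirichlet(np.ones(c))
        z = rng.normal(size=d)
        # naive direct summation
        total = 0.0
        for i in range(c):
            var = np.exp(-beta[i])
            total += w[i] * np.prod(norm.pdf(z, means[i], np.sqrt(var)))
        val = gmm_log_density(z, means, beta, np.log(w))
        assert val == pytest.approx(np.log(total), abs=1e-10)

    def test_no_overflow_far_from_means(self):
        d = 5
        z = np.full(d, 1e3)
        val = gmm_log_density(z, np.zeros((3, d)), np.ones((3, d)),
                              np.log(np.full(3, 1 / 3)))
        assert np.isfinite(val)

    def test_dimension_mismatch(self):
        with pytest.raises(ValueError):
            gmm_log_density(np.zeros(3), np.zeros((2, 4)), np.zeros((2, 4)),
                            np.log(np.full(2, 0.5)))

    def test_responsibilities_sum_to_one(self):
        rng = np.random.default_rng(0)
        resp = gmm_responsibilities(
            rng.normal(size=(7, 3)), rng.normal(size=(4, 3)),
            rng.normal(size=(4, 3)), np.log(rng.dirichlet(np.ones(4))))
        assert resp.shape == (7, 4)
        np.testing.assert_allclose(resp.sum(axis=1), 1.0, atol=1e-12)


class TestGMMParamLogPrior:
    SPREAD, SHARP, BMEAN, BSD, ALPHA = 7.0, 10.0, 1.0, 1.0, 5.0

    def _prior(self, means, beta, w):
        return gmm_param_log_prior(means, beta, w, self.SPREAD, self.SHARP,
                                   self.BMEAN, self.BSD, self.ALPHA)

    def test_beta_perturbation_changes_by_half(self):
        # moving one beta entry one prior sd off its mean costs exactly 0.5
        means = np.zeros((3, 4))
        w = np.full(3, 1 / 3)
        base = self._prior(means, np.full((3, 4), self.BMEAN), w)
        beta = np.full((3, 4), self.BMEAN)
        beta[1, 2] += self.BSD
        assert self._prior(means, beta, w) - base == pytest.approx(-0.5, abs=1e-12)

    def test_maximized_at_prior_modes(self):
        means = np.zeros((3, 4))
        w = np.full(3, 1 / 3)
        beta0 = np.full((3, 4), self.BMEAN)
        base = self._prior(means, beta0, w)
        assert self._prior(means + 0.5, beta0, w) < base
        assert self._prior(means, beta0 + 0.3, w) < base
        assert self._prior(means, beta0, np.array([0.5, 0.3, 0.2])) < base

    def test_term_by_term_oracle(self):
        rng = np.random.default_rng(11)
        c, d = 3, 4
        means = rng.normal(size=(c, d))
        beta = rng.normal(size=(c, d))
        w = rng.dirichlet(np.ones(c))
        expected = (
            sum(softball_log_density(means[i], self.SPREAD, self.SHARP)
                for i in range(c))
            + norm.logpdf(beta, self.BMEAN, self.BSD).sum()
            + sp_dirichlet.logpdf(w, np.full(c, self.ALPHA))
        )
        assert self._prior(means, beta, w) == pytest.approx(expected, abs=1e-10)
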