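import numpy as np
import pytest
from scipy import special, stats

from adelle.count_model import (BetaBinomialFit, fit_beta_binomial,
                                lvalue_lookup, pair_exceedance_prob,
                                precompute_lvalue_grid, s_moments, tail_prob)
from adelle.covariance import LowRankCorrelation


class TestPairExceedance:
    def test_independence_factorizes(self):
        for c in (0.5, 2.0, 4.0):
            p = tail_prob(c)
            np.testing.assert_allclose(pair_exceedance_prob(c, 0.0), p * p,
                                       rtol=1e-12)

    def test_perfect_correlation_collapses(self):
        for c in (0.5, 2.0):
            np.testing.assert_allclose(pair_exceedance_prob(c, 1.0),
                                       tail_prob(c), rtol=1e-6)

    def test_against_bivariate_normal_cdf(self):
        # independent oracle: scipy's bivariate normal orthant probabilities
        c, w = 1.96, 0.5
        lo = stats.multivariate_normal([0, 0], [[1, w], [w, 1]]).cdf([-c, -c])
        hi = stats.multivariate_normal([0, 0], [[1, -w], [-w, 1]]).cdf([-c, -c])
        np.testing.assert_allclose(pair_exceedance_prob(c, w), 2 * (lo + hi),
                                   atol=1e-8)

    def test_even_in_correlation(self):
        np.testing.assert_allclose(pair_exceedance_prob(1.5, 0.6),
                                   pair_exceedance_prob(1.5, -0.6), rtol=1e-12)

    def test_invalid_correlation_rejected(self):
        with pytest.raises(ValueError):
            pair_exceedance_prob(1.0, 1.5)


class TestSMoments:
    def test_identity_reduces_to_binomial(self):
        d, c = 40, 1.0
        mom = s_moments(c, np.eye(d))
        p = tail_prob(c)
        np.testing.assert_allclose(mom.mean, d * p, rtol=1e-12)
        np.testing.assert_allclose(mom.variance, d * p * (1 - p), rtol=1e-12)

    def test_two_point_distribution_at_full_correlation(self):
        mom = s_moments(1.0, np.array([[1.0, 1.0], [1.0, 1.0]]))
        p = tail_prob(1.0)
        np.testing.assert_allclose(mom.mean, 2 * p, rtol=1e-9)
        np.testing.assert_allclose(mom.variance, 4 * p * (1 - p), rtol=1e-6)

    def test_equicorrelated_against_simulation(self, rng):
        d, rho, c, n = 20, 0.3, 1.0, 200_000
        omega = (1 - rho) * np.eye(d) + rho
        mom = s_moments(c, omega)
        f = rng.standard_normal((n, 1))
        z = np.sqrt(rho) * f + np.sqrt(1 - rho) * rng.standard_normal((n, d))
        s = (np.abs(z) >= c).sum(axis=1)
        se_mean = s.std() / np.sqrt(n)
        assert abs(mom.mean - s.mean()) < 3 * se_mean
        se_var = s.var() * np.sqrt(2.0 / n)  # rough SE of a sample variance
        assert abs(mom.variance - s.var()) < 4 * se_var

    def test_factored_histogram_matches_dense_path(self, equicorr50):
        dense = s_moments(1.5, equicorr50.to_dense())
        summarized = s_moments(1.5, equicorr50)
        np.testing.assert_allclose(summarized.variance, dense.variance,
                                   rtol=1e-4)


class TestBetaBinomialFit:
    def test_binomial_boundary_falls_back(self):
        d, p = 30, 0.2
        fit = fit_beta_binomial(d, d * p, d * p * (1 - p))
        assert fit.fallback_binomial

    def test_moment_round_trip(self):
        f0 = BetaBinomialFit(d=10, p=0.4, alpha_bb=2.0, beta_bb=3.0,
                             fallback_binomial=False)
        mean, var = f0.moments()
        f1 = fit_beta_binomial(10, mean, var)
        np.testing.assert_allclose([f1.alpha_bb, f1.beta_bb], [2.0, 3.0],
                                   atol=1e-8)

    def test_tail_against_scipy_betabinom(self):
        f = BetaBinomialFit(d=25, p=0.3, alpha_bb=1.7, beta_bb=4.2,
                            fallback_binomial=False)
        got = f.upper_tail(25)
        expect = stats.betabinom.sf(np.arange(0, 25), 25, 1.7, 4.2)
        np.testing.assert_allclose(got, expect, atol=1e-12)

    def test_tail_against_sampler(self, rng):
        d, a, b, n = 15, 2.5, 6.0, 500_000
        f = BetaBinomialFit(d=d, p=a / (a + b), alpha_bb=a, beta_bb=b,
                            fallback_binomial=False)
        draws = rng.binomial(d, rng.beta(a, b, n))
        for dd in (1, 3, 7):
            emp = (draws >= dd).mean()
            se = np.sqrt(emp * (1 - emp) / n)
            assert abs(f.upper_tail(dd)[dd - 1] - emp) < 3.5 * se

    def test_invalid_moments_rejected(self):
        with pytest.raises(ValueError):
            fit_beta_binomial(10, 0.0, 1.0)
        with pytest.raises(ValueError):
            fit_beta_binomial(10, 2.0, 0.0)


class TestLValueGrid:
    def test_identity_grid_equals_beta_cdf(self):
        """Binomial-tail/beta identity: with Ω = I every grid row is the
        Beta(d, D−d+1) cdf at h."""
        d = 200
        grid = precompute_lvalue_grid(LowRankCorrelation.identity(d), q=0.2)
        dd = np.arange(1, grid.m + 1, dtype=float)[:, None]
        expect = special.betainc(dd, d - dd + 1.0, grid.h_grid[None, :])
        np.testing.assert_allclose(grid.table, expect, atol=1e-10)

    def test_monotone_in_h_and_d(self, random_lowrank300):
        grid = precompute_lvalue_grid(random_lowrank300, q=0.2)
        assert np.all(np.diff(grid.table, axis=1) >= 0)
        assert np.all(np.diff(grid.table, axis=0) <= 0)
        assert grid.table.min() >= 0 and grid.table.max() <= 1

    def test_first_row_is_one_minus_prob_zero(self, equicorr50):
        grid = precompute_lvalue_grid(equicorr50, q=0.2)
        for j in np.searchsorted(grid.h_grid, [1e-3, 1e-2, 0.15]):
            fit = BetaBinomialFit(d=50, p=float(tail_prob(
                -special.ndtri(grid.h_grid[j] / 2))),
                alpha_bb=grid.fit_alpha[j], beta_bb=grid.fit_beta[j],
                fallback_binomial=bool(grid.fit_fallback[j]))
            pmf0 = np.exp(fit._log_pmf_all()[0])
            np.testing.assert_allclose(grid.table[0, j], 1 - pmf0, atol=1e-10)

    def test_lookup_at_node_returns_stored_value(self, equicorr50):
        grid = precompute_lvalue_grid(equicorr50, q=0.2)
        j, d = 900, 4
        np.testing.assert_allclose(lvalue_lookup(grid, d, grid.h_grid[j]),
                                   grid.table[d - 1, j], rtol=1e-12)

    def test_lookup_brackets_between_nodes(self, equicorr50):
        grid = precompute_lvalue_grid(equicorr50, q=0.2)
        j, d = 700, 3
        h_mid = np.sqrt(grid.h_grid[j] * grid.h_grid[j + 1])
        val = lvalue_lookup(grid, d, h_mid)
        lo, hi = grid.table[d - 1, j], grid.table[d - 1, j + 1]
        assert lo <= val <= hi

    def test_lookup_against_direct_evaluation(self, random_lowrank300):
        """Grid interpolation vs gridless beta-binomial refit at the exact c."""
        grid = precompute_lvalue_grid(random_lowrank300, q=0.2)
        r = np.random.default_rng(17)
        worst = 0.0
        for _ in range(100):
            d = int(r.integers(1, grid.m + 1))
            p = float(10 ** r.uniform(-8, np.log10(0.2)))
            err = abs(lvalue_lookup(grid, d, p) - grid.direct_lvalue(d, p))
            worst = max(worst, err)
        assert worst <= 1e-4

    def test_event_identity(self, rng):
        """{π(d) ≤ h} and {S(−Φ⁻¹(h/2)) ≥ d} are the same event."""
        d, h, d_idx = 30, 0.05, 3
        z = rng.standard_normal((2000, d))
        p = special.erfc(np.abs(z) / np.sqrt(2))
        lhs = np.sort(p, axis=1)[:, d_idx - 1] <= h
        c = -special.ndtri(h / 2)
        rhs = (np.abs(z) >= c).sum(axis=1) >= d_idx
        np.testing.assert_array_equal(lhs, rhs)

    def test_h_outside_unit_interval_rejected(self, equicorr50):
        with pytest.raises(ValueError):
            precompute_lvalue_grid(equicorr50, q=0.2,
                                   h_grid=np.array([0.0, 0.5]))

    def test_save_load_round_trip(self, tmp_path, equicorr50):
        grid = precompute_lvalue_grid(equicorr50, q=0.2)
        path = tmp_path / "grid.h5"
        grid.save(path)
        from adelle.count_model import LValueGrid

        back = LValueGrid.load(path)
        np.testing.assert_array_equal(back.table, grid.table)
        assert back.d == grid.d and back.q == grid.q
        np.testing.assert_allclose(back.direct_lvalue(2, 1e-3),
                                   grid.direct_lvalue(2, 1e-3), rtol=1e-12)
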