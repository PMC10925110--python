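import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from adelle.covariance import (CorrelationEstimate, LowRankCorrelation,
                               _eigs_low_rank, _f1, cov2cor, estimate_omega,
                               masked_cross_product, sample_row_correlation,
                               shrink_eigenvalues)


class TestCov2Cor:
    def test_diagonal_matrix_becomes_identity(self):
        np.testing.assert_allclose(cov2cor(np.diag([2.0, 5.0, 9.0])), np.eye(3))

    def test_direct_arithmetic(self):
        out = cov2cor(np.array([[4.0, 2.0], [2.0, 9.0]]))
        np.testing.assert_allclose(out[0, 1], 2.0 / 6.0)
        np.testing.assert_allclose(np.diag(out), 1.0)

    def test_idempotent(self, rng):
        a = rng.standard_normal((6, 10))
        cov = a @ a.T
        once = cov2cor(cov)
        np.testing.assert_allclose(cov2cor(once), once, atol=1e-14)

    def test_nonpositive_diagonal_rejected(self):
        with pytest.raises(ValueError, match="diagonal"):
            cov2cor(np.array([[0.0, 0.0], [0.0, 1.0]]))


class TestSampleRowCorrelation:
    def test_identical_rows_correlate_fully(self, rng):
        row = rng.standard_normal(30)
        z = np.vstack([row, row, rng.standard_normal(30)])
        np.testing.assert_allclose(sample_row_correlation(z)[0, 1], 1.0)

    def test_orthogonal_centered_rows(self):
        z = np.array([[1.0, -1.0, 1.0, -1.0], [1.0, 1.0, -1.0, -1.0]])
        np.testing.assert_allclose(sample_row_correlation(z)[0, 1], 0.0,
                                   atol=1e-15)

    def test_matches_pairwise_pearson(self, rng):
        z = rng.standard_normal((6, 40))
        np.testing.assert_allclose(sample_row_correlation(z), np.corrcoef(z),
                                   atol=1e-12)

    def test_constant_row_rejected(self):
        with pytest.raises(ValueError, match="constant row"):
            sample_row_correlation(np.array([[1.0, 1.0], [0.0, 1.0]]))


class TestMaskedCrossProduct:
    def test_full_mask_reduces_to_plain_cross_product(self, rng):
        z = rng.standard_normal((4, 12))
        mask = np.ones((12, 4), dtype=bool)
        got = masked_cross_product(z, mask).vhat1
        zc = z - z.mean(axis=1, keepdims=True)
        np.testing.assert_allclose(got, zc @ zc.T, atol=1e-12)

    def test_brute_force_oracle(self, rng):
        d, m = 3, 4
        z = rng.standard_normal((d, m))
        mask = np.array([[1, 1, 0], [1, 0, 1], [1, 1, 1], [0, 1, 1]], dtype=bool)
        got = masked_cross_product(z, mask)
        zbar = np.array([z[i, mask[:, i]].mean() for i in range(d)])
        expect = np.zeros((d, d))
        for i in range(d):
            for j in range(d):
                for s in range(m):
                    if mask[s, i] and mask[s, j]:
                        expect[i, j] += (z[i, s] - zbar[i]) * (z[j, s] - zbar[j])
        np.testing.assert_allclose(got.vhat1, expect, atol=1e-12)
        np.testing.assert_allclose(got.row_means, zbar)

    def test_disjoint_pair_policy(self, rng):
        z = rng.standard_normal((3, 6))
        mask = np.zeros((6, 3), dtype=bool)
        mask[:3, 0] = True
        mask[3:, 1] = True
        mask[:, 2] = True
        with pytest.raises(ValueError, match="share no SNP"):
            masked_cross_product(z, mask)
        with pytest.warns(UserWarning):
            out = masked_cross_product(z, mask, zero_policy="zero")
        assert out.vhat1[0, 1] == 0.0


class TestShrinkage:
    def _spiked(self, rng, d=200, rank=50, spikes=(60, 40, 25)):
        lam = np.zeros(d)
        lam[:rank] = np.sort(rng.uniform(0.5, 2.0, rank))[::-1]
        lam[:len(spikes)] += spikes
        return lam / lam.sum() * d

    def test_trace_preserved_and_ab_in_range(self, rng):
        for _ in range(10):
            lam = self._spiked(rng)
            shrunk, lam_plus, u, a, b = shrink_eigenvalues(lam, 4.0)
            assert abs(shrunk.sum() - 200) < 1e-8
            assert a > 0 and 0 < b < 1
            assert np.all(np.diff(shrunk) <= 1e-12)

    def test_ab_solve_matches_independent_linear_system(self, rng):
        lam = self._spiked(rng)
        gamma = 4.0
        shrunk, lam_plus, u, a, b = shrink_eigenvalues(lam, gamma)
        large = lam > lam_plus
        mat = np.array([[1.0, lam_plus],
                        [float((~large).sum()), lam[~large].sum()]])
        rhs = np.array([_f1(lam_plus, gamma),
                        200.0 - _f1(lam[large], gamma).sum()])
        ab = np.linalg.solve(mat, rhs)
        np.testing.assert_allclose([a, b], ab, atol=1e-10)

    def test_f1_identity_as_gamma_vanishes(self):
        lam = np.array([1.5, 2.0, 10.0])
        np.testing.assert_allclose(_f1(lam, 1e-12), lam, rtol=1e-9)

    def test_f1_shrinks_downward(self):
        gamma = 3.0
        lam = np.linspace((1 + gamma) ** 2 + 1, 200, 50)
        assert np.all(_f1(lam, gamma) <= lam)

    def test_unsorted_rejected(self):
        with pytest.raises(ValueError, match="sorted"):
            shrink_eigenvalues(np.array([1.0, 2.0]), 2.0)


class TestEstimateOmega:
    @given(st.integers(0, 19))
    @settings(deadline=None, max_examples=20)
    def test_invariants_on_random_inputs(self, seed):
        r = np.random.default_rng(seed)
        d, m = 60, 200
        z = r.standard_normal((d, m)) + 0.5 * r.standard_normal((1, m))
        est = estimate_omega(z, seed=seed)
        dense = est.structure.to_dense()
        np.testing.assert_allclose(np.diag(dense), 1.0, atol=1e-10)
        eigs = np.linalg.eigvalsh(dense)
        assert eigs.min() >= -1e-8
        assert abs(est.shrunk_eigs.sum() - d) < 1e-8
        a, b = est.contraction
        assert a > 0 and 0 < b < 1

    def test_sampling_factor_reproduces_omega(self, rng):
        z = rng.standard_normal((30, 100))
        est = estimate_omega(z, seed=0)
        f = est.sampling_factor
        np.testing.assert_allclose(f @ f.T, est.omega_hat, atol=1e-8)

    def test_independent_traits_give_small_offdiagonals(self):
        r = np.random.default_rng(5)
        z = r.standard_normal((100, 5000))
        est = estimate_omega(z, seed=0)
        off = est.omega_hat - np.eye(100)
        assert np.abs(off).max() <= 0.1

    def test_gamma_is_dim_over_rank(self):
        r = np.random.default_rng(6)
        z = r.standard_normal((100, 49)) @ r.standard_normal((49, 400))
        est = estimate_omega(z, seed=0)
        assert est.rank_used == 49
        np.testing.assert_allclose(est.gamma, 100 / 49)

    def test_shrinkage_improves_frobenius_error(self):
        """Ω̂ should beat the raw sample correlation Ω̂1 on average."""
        d, n, m = 200, 50, 2000
        rho = 0.5
        block = 10
        from adelle.simulation import OmegaSpec, make_omega_true, simulate_cy

        omega = make_omega_true(OmegaSpec(kind="block", rho=rho,
                                          block_size=block), d)
        truth = omega.to_dense()
        wins = 0
        for seed in range(10):
            ss = np.random.SeedSequence(seed)
            ts = simulate_cy(n, omega, ss)
            rng2 = np.random.default_rng(ss.spawn(1)[0])
            z = ts.cy.rvs(m, rng2).T
            raw = sample_row_correlation(z)
            est = estimate_omega(z, rank=n - 1, seed=seed)
            err_raw = np.linalg.norm(raw - truth)
            err_shrunk = np.linalg.norm(est.omega_hat - truth)
            wins += err_shrunk < err_raw
        assert wins >= 8

    def test_low_rank_eigen_path_matches_operator(self, rng):
        """Randomized eigenpairs reproduce H Hᵀ action on probe vectors."""
        h = rng.standard_normal((2600, 40)) @ rng.standard_normal((40, 300))
        vals, vecs = _eigs_low_rank(h, rank_hint=40, rng=rng)
        probe = rng.standard_normal((2600, 3))
        direct = h @ (h.T @ probe)
        recon = vecs @ (vals[:, None] * (vecs.T @ probe))
        np.testing.assert_allclose(recon, direct, atol=1e-6 * np.abs(direct).max())

    def test_subset_keeps_unit_diagonal(self, random_lowrank300, rng):
        idx = rng.choice(300, 40, replace=False)
        sub = random_lowrank300.subset(np.sort(idx))
        np.testing.assert_allclose(np.diag(sub.to_dense()), 1.0, atol=1e-12)


class TestPersistence:
    def test_save_load_round_trip(self, tmp_path, rng):
        z = rng.standard_normal((25, 80))
        est = estimate_omega(z, seed=0)
        path = tmp_path / "omega.h5"
        est.save(path)
        back = CorrelationEstimate.load(path)
        np.testing.assert_array_equal(back.structure.weights,
                                      est.structure.weights)
        assert back.fingerprint() == est.fingerprint()
        assert back.contraction == est.contraction
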