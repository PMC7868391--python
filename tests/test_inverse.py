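"""Inverse solvers: covariance/CSD estimation, regularization rules,
LCMV/DICS beamformers, sLORETA and eLORETA."""

import warnings

import numpy as np
import pytest
from scipy.stats import spearmanr

from ratesi import inverse as iv
from ratesi.forward import LeadField


def _single_dipole_data(lf, p, axis, T, rng, noise=0.0):
    x = np.outer(lf.K[:, p, axis], rng.standard_normal(T))
    if noise:
        x = x + noise * np.abs(lf.K).max() * rng.standard_normal(x.shape)
    return x


class TestCovariance:
    def test_identical_columns_give_zero(self):
        X = np.tile(np.arange(4.0)[:, None], (1, 50))
        cov = iv.estimate_covariance(X)
        assert np.abs(cov.C).max() == 0.0

    def test_white_data_diagonal_near_one(self, rng):
        T = 100_000
        X = rng.standard_normal((6, T))
        cov = iv.estimate_covariance(X)
        assert np.abs(np.diag(cov.C) - 1).max() < 3 / np.sqrt(T)
        off = cov.C - np.diag(np.diag(cov.C))
        assert np.abs(off).max() < 4 / np.sqrt(T)   # max over 15 pairs

    def test_rank_bounded_by_samples(self, rng):
        X = rng.standard_normal((8, 5))
        cov = iv.estimate_covariance(X)
        assert np.linalg.matrix_rank(cov.C) <= 4

    def test_single_sample_raises(self):
        with pytest.raises(ValueError):
            iv.estimate_covariance(np.ones((3, 1)))


class TestCSD:
    def test_identical_sinusoids_fully_coherent(self):
        t = np.arange(1000) / 1000.0
        s = np.sin(2 * np.pi * 43 * t)
        trials = np.stack([np.vstack([s, s]) for _ in range(5)])
        csd = iv.estimate_csd(trials, 43, 1000)
        coh = np.abs(csd.C[0, 1]) / np.sqrt(csd.C[0, 0].real
                                            * csd.C[1, 1].real)
        assert coh == pytest.approx(1.0, abs=1e-10)

    def test_independent_channels_decorrelate(self, rng):
        n_trials = 400
        trials = rng.standard_normal((n_trials, 2, 256))
        csd = iv.estimate_csd(trials, 43, 1000)
        coh = np.abs(csd.C[0, 1]) / np.sqrt(csd.C[0, 0].real
                                            * csd.C[1, 1].real)
        assert coh < 3 / np.sqrt(n_trials)

    def test_hermitian_output(self, rng):
        trials = rng.standard_normal((3, 4, 500))
        csd = iv.estimate_csd(trials, 43, 1000)
        assert np.allclose(csd.C, csd.C.conj().T)

    def test_frequency_above_nyquist_raises(self, rng):
        with pytest.raises(ValueError, match="Nyquist"):
            iv.estimate_csd(rng.standard_normal((2, 2, 100)), 600, 1000)


class TestRegularization:
    @pytest.mark.parametrize("eigs,expected", [
        ((10.0, 1.0), 0.03),
        ((1.0, 1.0, 1.0), 0.003),
        ((0.0, 0.0), 0.0),
    ])
    def test_eigenvalue_rule(self, eigs, expected):
        C = np.diag(np.asarray(eigs, dtype=float))
        assert iv.reg_from_eigenvalue(C) == pytest.approx(expected)

    def test_inverse_mode_uses_smallest_nonnull(self):
        C = np.diag([10.0, 2.0, 1e-15])
        assert iv.reg_from_eigenvalue(C, mode="inverse") == \
            pytest.approx(0.003 / 2.0)

    def test_loocv_prefers_small_gamma_for_noiseless_data(self, tiny_lf, rng):
        X = _single_dipole_data(tiny_lf, 7, 1, 40, rng)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            g = iv.reg_loocv(tiny_lf, X, solver="sloreta",
                             gammas=[1e-8, 1.0])
        assert g == 1e-8

    def test_loocv_single_value_short_circuits(self, tiny_lf, rng):
        X = rng.standard_normal((12, 10))
        assert iv.reg_loocv(tiny_lf, X, gammas=[0.42]) == 0.42

    def test_loocv_empty_grid_raises(self, tiny_lf, rng):
        with pytest.raises(ValueError, match="empty"):
            iv.reg_loocv(tiny_lf, rng.standard_normal((12, 10)), gammas=[])


class TestLCMV:
    def test_unit_gain_constraint(self, small_lf, rng):
        X = _single_dipole_data(small_lf, 3, 0, 100, rng, noise=0.05)
        fb, _ = iv.lcmv(small_lf, iv.estimate_covariance(X), gamma=0.0)
        wg = np.einsum("pin,npj->pij", fb.filters, small_lf.K)
        assert np.abs(wg - np.eye(3)).max() < 1e-10

    def test_nai_is_one_under_identity_covariance(self, small_lf):
        cov = iv.CovarianceModel(C=np.eye(12))
        _, sm = iv.lcmv(small_lf, cov, gamma=0.0)
        assert np.allclose(sm.activity, 1.0)

    def test_matches_dense_per_dipole_oracle(self, rng):
        # brute-force evaluation of the minimum-variance expressions,
        # dipole by dipole with explicit dense algebra
        N, P = 6, 20
        K = rng.standard_normal((N, P, 3))
        grid = None
        lf = LeadField(K=K, montage=None, grid=grid, referencing="raw")
        C = rng.standard_normal((N, 40))
        C = C @ C.T / 40
        gamma = 0.01
        fb, sm = iv.lcmv(lf, iv.CovarianceModel(C=C), gamma=gamma)
        Cinv = np.linalg.inv(C + gamma * np.eye(N))
        for p in range(P):
            Kp = K[:, p, :]
            Ainv = np.linalg.inv(Kp.T @ Cinv @ Kp)
            w = Ainv @ Kp.T @ Cinv
            var = np.trace(Ainv)
            nai = var / np.trace(np.linalg.inv(Kp.T @ Kp))
            assert np.allclose(fb.filters[p], w, atol=1e-10 * np.abs(w).max())
            assert sm.activity[p] == pytest.approx(nai, rel=1e-10)

    def test_two_source_toy_maxima_at_active_dipoles(self, rng):
        N, P, T = 8, 24, 5000
        K = rng.standard_normal((N, P, 3))
        lf = LeadField(K=K, montage=None, grid=None, referencing="raw")
        s = rng.standard_normal((2, T))
        X = (np.outer(K[:, 4, 0], s[0]) + np.outer(K[:, 17, 2], s[1])
             + 0.05 * rng.standard_normal((N, T)))
        _, sm = iv.lcmv(lf, iv.estimate_covariance(X))
        top2 = set(np.argsort(sm.activity)[-2:].tolist())
        assert top2 == {4, 17}


class TestDICS:
    def test_identity_csd_gives_unit_nai(self, small_lf):
        csd = iv.CovarianceModel(C=np.eye(12, dtype=complex), kind="csd")
        _, sm = iv.dics(small_lf, csd, gamma=0.0)
        assert np.allclose(sm.activity, 1.0)

    def test_narrowband_dics_matches_lcmv(self, small_lf, rng):
        t = np.arange(2000) / 1000.0
        p = 40
        trials = np.stack([
            np.outer(small_lf.K[:, p, 2],
                     np.sin(2 * np.pi * 43 * t + rng.uniform(0, 2 * np.pi)))
            + 1e-3 * np.abs(small_lf.K[:, p, 2]).max()
            * rng.standard_normal((12, 2000))
            for _ in range(20)])
        csd = iv.estimate_csd(trials, 43, 1000)
        _, smd = iv.dics(small_lf, csd)
        cov = iv.estimate_covariance(list(trials))
        _, sml = iv.lcmv(small_lf, cov)
        rho = spearmanr(smd.activity, sml.activity).statistic
        assert rho > 0.95

    def test_planted_43hz_source_localized(self, small_lf, small_head, rng):
        t = np.arange(2000) / 1000.0
        p = int(np.argmax(small_head.grid.positions[:, 2]))  # shallow dipole
        trials = np.stack([
            np.outer(small_lf.K[:, p, 2],
                     np.sin(2 * np.pi * 43 * t + rng.uniform(0, 2 * np.pi)))
            + 1e-3 * np.abs(small_lf.K[:, p, 2]).max()
            * rng.standard_normal((12, 2000))
            for _ in range(20)])
        csd = iv.estimate_csd(trials, 43, 1000)
        _, sm = iv.dics(small_lf, csd,
                        gamma=iv.reg_from_eigenvalue(csd, mode="inverse"))
        d = np.linalg.norm(small_head.grid.positions[sm.argmax()]
                           - small_head.grid.positions[p])
        assert d <= 2.0  # within two 1-mm grid steps


class TestSLORETA:
    def test_zero_data_gives_zero_map(self, small_lf):
        sm = iv.sloreta(small_lf, np.zeros((12, 10)), gamma=1e-3)
        assert np.all(sm.activity == 0)

    def test_negative_gamma_raises(self, small_lf, rng):
        with pytest.raises(ValueError):
            iv.sloreta(small_lf, rng.standard_normal((12, 10)), gamma=-1.0)

    def test_noiseless_single_source_zero_location_error(self, small_lf,
                                                         small_head, rng):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            for p in rng.choice(small_lf.n_dipoles, 25, replace=False):
                for axis in range(3):
                    x = _single_dipole_data(small_lf, p, axis, 20, rng)
                    sm = iv.sloreta(small_lf, x, gamma=1e-12)
                    assert sm.argmax() == p

    def test_default_gamma_is_five_percent_of_diagonal(self, small_lf, rng):
        X = rng.standard_normal((12, 200))
        sm = iv.sloreta(small_lf, X)
        xc = X - X.mean(axis=1, keepdims=True)
        expect = 0.05 * np.mean(np.sum(xc * xc, axis=1) / 199)
        assert sm.gamma == pytest.approx(expect)


class TestELORETA:
    def test_fixed_point_residual(self, small_lf):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            W, n_iter = iv.eloreta_weights(small_lf, gamma=0.0, tol=1e-8,
                                           max_iter=500)
            K = small_lf.K
            Winv = np.linalg.inv(W)
            M = iv._pinvh(np.einsum("npi,pij,mpj->nm", K, Winv, K))
            W_fix = iv._sqrtm_spd(np.einsum("npi,nm,mpj->pij", K, M, K))
        res = np.linalg.norm(W_fix - W) / np.linalg.norm(W)
        assert res < 1e-7

    def test_matches_tighter_tolerance_run(self, tiny_lf):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            W1, _ = iv.eloreta_weights(tiny_lf, gamma=0.0, tol=1e-6)
            W2, _ = iv.eloreta_weights(tiny_lf, gamma=0.0, tol=1e-7,
                                       max_iter=1000)
        assert np.abs(W1 - W2).max() / np.abs(W2).max() < 1e-4

    def test_single_channel_raises(self, tiny_lf):
        lf1 = LeadField(K=tiny_lf.K[:1], montage=tiny_lf.montage,
                        grid=tiny_lf.grid, referencing="raw")
        with pytest.raises(ValueError, match="channels"):
            iv.eloreta_weights(lf1)

    def test_zero_data_gives_zero_map(self, small_lf):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            sm = iv.eloreta(small_lf, np.zeros((12, 5)))
        assert np.all(sm.activity == 0)

    def test_quadratic_scaling_with_fixed_filters(self, small_lf, rng):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fb = iv.eloreta_filters(small_lf, gamma=0.0)
        x = _single_dipole_data(small_lf, 5, 0, 10, rng)
        a1 = iv.eloreta(small_lf, x, filters=fb).activity
        a2 = iv.eloreta(small_lf, 2 * x, filters=fb).activity
        assert np.allclose(a2, 4 * a1, rtol=1e-12)

    def test_exact_localization_sample(self, small_lf, rng):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fb = iv.eloreta_filters(small_lf, gamma=0.0)
        for p in rng.choice(small_lf.n_dipoles, 25, replace=False):
            for axis in range(3):
                x = _single_dipole_data(small_lf, p, axis, 15, rng)
                sm = iv.eloreta(small_lf, x, filters=fb)
                assert sm.argmax() == p
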