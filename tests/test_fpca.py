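"""Sparse FPCA: mean, covariance surface, eigenstructure, BLUP curves."""

import numpy as np
import pytest
from scipy import linalg

from fcreg import (
    ObservedFunction,
    blup_curve,
    build_basis,
    eigendecompose,
    estimate_covariance,
    estimate_mean,
    evaluate_basis,
)
from fcreg.basis import gram_matrix
from fcreg.exceptions import IdentifiabilityError
from fcreg.fpca import CovarianceModel, project_psd


def _make_funcs(rng, n, m, curve, noise_sd):
    out = []
    for _ in range(n):
        t = np.sort(rng.uniform(0, 1, size=m))
        out.append(ObservedFunction(t, curve(t, rng) + noise_sd * rng.normal(size=m)))
    return out


class TestEstimateMean:
    def test_zero_data_gives_zero_mean(self, unit_basis, rng):
        funcs = _make_funcs(rng, 30, 12, lambda t, r: np.zeros_like(t), 0.0)
        coefs = estimate_mean(funcs, unit_basis)
        assert np.abs(coefs).max() < 1e-10

    def test_constant_data_reproduced_exactly(self, unit_basis, rng):
        funcs = _make_funcs(rng, 20, 10, lambda t, r: np.full_like(t, 3.5), 0.0)
        coefs = estimate_mean(funcs, unit_basis)
        t = np.linspace(0.01, 0.99, 100)
        np.testing.assert_allclose(
            evaluate_basis(unit_basis, t) @ coefs, 3.5, atol=1e-8
        )

    def test_sine_mean_recovered(self, rng):
        funcs = _make_funcs(
            rng, 200, 20, lambda t, r: np.sin(2 * np.pi * t), 0.01
        )
        basis = build_basis(np.concatenate([f.times for f in funcs]))
        coefs = estimate_mean(funcs, basis)
        t = np.linspace(*basis.boundary, 500)
        err = evaluate_basis(basis, t) @ coefs - np.sin(2 * np.pi * t)
        assert np.trapezoid(err**2, t) < 1e-2


class TestEstimateCovariance:
    def test_two_eigenfunction_recovery(self):
        """Median recovery of eigenvalues and nugget over repeated draws."""
        lam_true = np.array([0.6, 0.2])
        phis = [lambda t: np.ones_like(t), lambda t: np.sqrt(2) * np.cos(2 * np.pi * t)]
        lam_est, nug_est = [], []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            funcs = []
            for _ in range(200):
                t = np.sort(rng.uniform(0, 1, size=20))
                xi = rng.normal(size=2) * np.sqrt(lam_true)
                y = xi[0] * phis[0](t) + xi[1] * phis[1](t)
                funcs.append(ObservedFunction(t, y + 0.1 * rng.normal(size=20)))
            basis = build_basis(np.concatenate([f.times for f in funcs]))
            model = estimate_covariance(funcs, np.zeros(basis.c), basis)
            lam_est.append(model.eigenvalues[:2])
            nug_est.append(model.error_var)
        lam_med = np.median(np.array(lam_est), axis=0)
        assert np.all(np.abs(lam_med - lam_true) / lam_true < 0.15)
        assert abs(np.median(nug_est) - 0.01) / 0.01 < 0.20

    def test_exact_span_recovery_without_smoothing(self, unit_basis, rng):
        """Noiseless curves in span{B} with empirical score covariance exactly
        Gamma are recovered by the unpenalized cross-product regression."""
        c = unit_basis.c
        R = rng.normal(size=(c, c))
        gamma_true = R @ R.T / c
        n = 64
        # orthogonal score design: scores with exact second moment Gamma
        Q, _ = np.linalg.qr(rng.normal(size=(n, c)))
        scores = Q * np.sqrt(n) @ np.linalg.cholesky(gamma_true).T
        t = np.linspace(0.0, 1.0, 30)
        B = evaluate_basis(unit_basis, t)
        funcs = [ObservedFunction(t, B @ u) for u in scores]
        model = estimate_covariance(
            funcs, np.zeros(c), unit_basis, lambdas=np.array([1e-8])
        )
        rel = np.linalg.norm(model.gamma - gamma_true) / np.linalg.norm(gamma_true)
        assert rel < 0.05

    def test_zero_residuals_give_zero_model(self, unit_basis, rng):
        funcs = _make_funcs(rng, 20, 8, lambda t, r: np.zeros_like(t), 0.0)
        model = estimate_covariance(funcs, np.zeros(unit_basis.c), unit_basis)
        assert np.abs(model.gamma).max() < 1e-10
        assert model.error_var == 0.0

    def test_no_offdiagonal_pairs_raises(self, unit_basis):
        funcs = [ObservedFunction([0.3], [1.0]), ObservedFunction([0.7], [2.0])]
        with pytest.raises(IdentifiabilityError):
            estimate_covariance(funcs, np.zeros(unit_basis.c), unit_basis)

    def test_surface_symmetric_and_projection_idempotent(self, unit_basis, rng):
        funcs = _make_funcs(
            rng, 60, 12,
            lambda t, r: r.normal() + r.normal() * np.sin(np.pi * t), 0.1,
        )
        model = estimate_covariance(funcs, np.zeros(unit_basis.c), unit_basis)
        s = np.sort(rng.uniform(0, 1, 40))
        C = model.cov_between(s, s)
        assert np.abs(C - C.T).max() < 1e-10
        np.testing.assert_allclose(
            project_psd(model.gamma), model.gamma, atol=1e-10
        )
        assert np.linalg.eigvalsh(model.gamma).min() > -1e-12

    def test_eigenvalue_error_shrinks_with_sample_size(self):
        """Consistency smoke test: N=1000 beats N=200 for the top eigenvalue."""
        lam_true = np.array([0.6, 0.2])
        errs = {}
        for n in (200, 1000):
            rng = np.random.default_rng(7)
            funcs = []
            for _ in range(n):
                t = np.sort(rng.uniform(0, 1, size=20))
                xi = rng.normal(size=2) * np.sqrt(lam_true)
                y = xi[0] + xi[1] * np.sqrt(2) * np.cos(2 * np.pi * t)
                funcs.append(ObservedFunction(t, y + 0.1 * rng.normal(size=20)))
            basis = build_basis(np.concatenate([f.times for f in funcs]))
            model = estimate_covariance(funcs, np.zeros(basis.c), basis)
            errs[n] = np.abs(model.eigenvalues[:2] - lam_true).sum()
        assert errs[1000] < errs[200]


class TestEigendecompose:
    def _orthonormal_gamma(self, basis, lam):
        G = gram_matrix(basis)
        w, U = linalg.eigh(G)
        W_inv = (U / np.sqrt(w)) @ U.T
        V = W_inv[:, : len(lam)]  # L2-orthonormal coefficient vectors
        return (V * lam) @ V.T, V

    def test_construction_inverse(self, unit_basis):
        lam = np.array([2.0, 0.5, 0.1])
        gamma, _ = self._orthonormal_gamma(unit_basis, lam)
        model = CovarianceModel(unit_basis, np.zeros(unit_basis.c), gamma, 0.0)
        evals, coeffs = eigendecompose(model)
        np.testing.assert_allclose(evals[:3], lam, atol=1e-8)
        # eigenfunctions L2-orthonormal
        G = gram_matrix(unit_basis)
        np.testing.assert_allclose(
            coeffs.T @ G @ coeffs, np.eye(coeffs.shape[1]), atol=1e-6
        )

    def test_rank_one_gamma(self, unit_basis):
        gamma, _ = self._orthonormal_gamma(unit_basis, np.array([1.3]))
        model = CovarianceModel(unit_basis, np.zeros(unit_basis.c), gamma, 0.0)
        evals, _ = eigendecompose(model)
        assert abs(evals[0] - 1.3) < 1e-8
        assert np.all(np.abs(evals[1:]) < 1e-10)

    def test_trace_identity_random_psd(self, unit_basis, rng):
        R = rng.normal(size=(unit_basis.c, unit_basis.c))
        gamma = R @ R.T
        model = CovarianceModel(unit_basis, np.zeros(unit_basis.c), gamma, 0.0)
        evals, _ = eigendecompose(model)
        grid = np.linspace(0, 1, 4001)
        diag = model.var_at(grid)
        integral = np.trapezoid(diag, grid)
        assert abs(evals.sum() - integral) / integral < 1e-4


class TestBlupCurve:
    def _random_model(self, basis, rng, error_var=0.05):
        R = rng.normal(size=(basis.c, basis.c))
        gamma = R @ R.T / basis.c
        mean = rng.normal(size=basis.c)
        return CovarianceModel(basis, mean, gamma, error_var)

    def test_noiseless_interpolation(self, unit_basis, rng):
        model = self._random_model(unit_basis, rng, error_var=0.0)
        t = np.array([0.2, 0.5, 0.8])
        vals = rng.normal(size=3)
        obs = ObservedFunction(t, vals)
        pred, var = blup_curve(model, obs, t)
        np.testing.assert_allclose(pred, vals, atol=1e-6)
        assert np.all(var < 1e-6)

    def test_no_observations_returns_prior(self, unit_basis, rng):
        model = self._random_model(unit_basis, rng)
        t = np.linspace(0.1, 0.9, 10)
        pred, var = blup_curve(model, None, t)
        np.testing.assert_allclose(pred, model.mean_at(t), atol=1e-12)
        np.testing.assert_allclose(var, model.var_at(t), atol=1e-12)

    def test_joint_gaussian_oracle(self, unit_basis, rng):
        """BLUP equals conditional mean/variance from the full joint covariance."""
        model = self._random_model(unit_basis, rng)
        t_obs = np.sort(rng.uniform(0, 1, size=5))
        t_new = np.sort(rng.uniform(0, 1, size=7))
        z = rng.normal(size=5)
        pred, var = blup_curve(model, ObservedFunction(t_obs, z), t_new)
        # oracle: build the joint covariance of (Z_obs, Z(t_new)) and condition
        t_all = np.concatenate([t_obs, t_new])
        C = model.cov_between(t_all, t_all)
        C[:5, :5] += model.error_var * np.eye(5)
        mu = model.mean_at(t_all)
        K_inv = np.linalg.inv(C[:5, :5])
        mu_cond = mu[5:] + C[5:, :5] @ K_inv @ (z - mu[:5])
        var_cond = np.diag(C[5:, 5:] - C[5:, :5] @ K_inv @ C[:5, 5:])
        np.testing.assert_allclose(pred, mu_cond, atol=1e-8)
        np.testing.assert_allclose(var, var_cond, atol=1e-8)

    def test_variance_never_exceeds_prior(self, unit_basis, rng):
        model = self._random_model(unit_basis, rng)
        t_new = np.linspace(0, 1, 50)
        for m in (1, 3, 8):
            obs = ObservedFunction(
                np.sort(rng.uniform(0, 1, m)), rng.normal(size=m)
            )
            _, var = blup_curve(model, obs, t_new)
            assert np.all(var <= model.var_at(t_new) + 1e-10)

    def test_extra_observation_never_increases_variance(self, unit_basis, rng):
        model = self._random_model(unit_basis, rng)
        t_new = np.linspace(0, 1, 30)
        t_obs = np.sort(rng.uniform(0, 1, size=6))
        vals = rng.normal(size=6)
        _, var_small = blup_curve(model, ObservedFunction(t_obs[:-1], vals[:-1]), t_new)
        _, var_full = blup_curve(model, ObservedFunction(t_obs, vals), t_new)
        assert np.all(var_full <= var_small + 1e-10)
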