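"""Penalized GLS core: design assembly, Eq-oracle equivalence, smoothing, 4-step fit."""

import numpy as np
import pytest
from scipy import linalg

from fcreg import (
    CovarianceModel,
    ObservedSubject,
    assemble_design,
    build_basis,
    coefficient_function,
    evaluate_basis,
    fit_fcr,
    pgls_solve,
    select_smoothing,
)
from fcreg.basis import difference_penalty
from fcreg.exceptions import MissingDataError
from fcreg.model import (
    DesignBlock,
    _whitened_crossproducts,
    reml_criterion,
)
from fcreg.simulate import SimulationScenario, generate_dataset


def _random_instance(rng, n_subjects=8, c=6, n_cov=1):
    """A random small penalized-GLS instance with PSD per-subject V."""
    basis = build_basis(rng.uniform(size=60), n_interior=c - 4, order=4)
    R = rng.normal(size=(basis.c, basis.c))
    gamma = R @ R.T / basis.c
    sigma2 = 0.3 + rng.uniform()
    blocks = []
    for i in range(n_subjects):
        m = rng.integers(5, 12)
        t = np.sort(rng.uniform(*basis.boundary, size=m))
        B = evaluate_basis(basis, t)
        cols = [B]
        zs = []
        for _ in range(n_cov):
            z = rng.normal(size=m)
            zs.append(z)
            cols.append(z[:, None] * B)
        X = np.hstack(cols)
        y = rng.normal(size=m)
        blocks.append(DesignBlock(i, t, y, X, np.column_stack(zs) if zs else
                                  np.empty((m, 0))))
    lambdas = 10.0 ** rng.uniform(-2, 2, size=n_cov + 1)
    return basis, blocks, gamma, sigma2, lambdas


def eq3_dense_oracle(blocks, basis, gamma, sigma2, lambdas, penalty):
    """Literal dense assembly of the penalized-GLS estimator and sandwich."""
    N = len(blocks)
    q = blocks[0].X.shape[1]
    n_blocks = q // basis.c
    info = np.zeros((q, q))
    score = np.zeros(q)
    for b in blocks:
        Bmat = b.X[:, : basis.c]
        V = Bmat @ gamma @ Bmat.T + sigma2 * np.eye(b.m) if gamma is not None \
            else sigma2 * np.eye(b.m)
        Vinv = np.linalg.inv(V)
        info += b.X.T @ Vinv @ b.X
        score += b.X.T @ Vinv @ b.y
    P = np.zeros((q, q))
    for p in range(n_blocks):
        sl = slice(p * basis.c, (p + 1) * basis.c)
        P[sl, sl] = lambdas[p] * penalty.matrix
    A = info / N + P
    theta = np.linalg.solve(A, score / N)
    A_inv = np.linalg.inv(A)
    cov = A_inv @ (info / N**2) @ A_inv
    return theta, cov


class TestAssembleDesign:
    def test_intercept_only_design_is_basis(self, small_dataset):
        basis = build_basis(np.concatenate([s.times for s in small_dataset.train]))
        blocks = assemble_design(small_dataset.train, basis)
        for s, b in zip(small_dataset.train, blocks):
            np.testing.assert_array_equal(b.X, evaluate_basis(basis, s.times))

    def test_unit_binary_covariate_duplicates_basis_block(self, unit_basis):
        s = ObservedSubject("a", [0.1, 0.4, 0.9], [1.0, 2.0, 3.0],
                            covariates={"male": 1.0})
        blocks = assemble_design([s], unit_basis, covariates=["male"])
        c = unit_basis.c
        np.testing.assert_array_equal(blocks[0].X[:, :c], blocks[0].X[:, c:])

    def test_noiseless_covariate_block_equals_observations(self, unit_basis, rng):
        t = np.sort(rng.uniform(0, 1, size=8))
        z = rng.normal(size=8)
        s = ObservedSubject("a", t, rng.normal(size=8), tvc={"waz": z})
        model = CovarianceModel(
            unit_basis, np.zeros(unit_basis.c), np.eye(unit_basis.c),
            error_var=0.0,
        )
        blocks = assemble_design([s], unit_basis, tvc=["waz"],
                                 covariate_models={"waz": model})
        np.testing.assert_allclose(blocks[0].z[:, 0], z, atol=1e-6)

    def test_missing_covariate_model_raises(self, unit_basis):
        s = ObservedSubject("a", [0.1, 0.5], [1.0, 2.0], tvc={"waz": [0.0, 1.0]})
        with pytest.raises(MissingDataError):
            assemble_design([s], unit_basis, tvc=["waz"])


class TestPglsSolve:
    def test_reduces_to_ols_without_penalty_or_random_effects(self, rng):
        basis, blocks, _, _, _ = _random_instance(rng)
        q = blocks[0].X.shape[1]
        theta, _ = pgls_solve(blocks, basis, None, 1.0, np.zeros(2))
        X = np.vstack([b.X for b in blocks])
        y = np.concatenate([b.y for b in blocks])
        expected, *_ = np.linalg.lstsq(X, y, rcond=None)
        np.testing.assert_allclose(theta, expected, atol=1e-8)

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_dense_assembly_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n_cov = int(rng.integers(0, 3))
        basis, blocks, gamma, sigma2, lambdas = _random_instance(
            rng, n_subjects=int(rng.integers(3, 10)),
            c=int(rng.integers(4, 7)), n_cov=n_cov,
        )
        penalty = difference_penalty(basis.c)
        theta, cov = pgls_solve(blocks, basis, gamma, sigma2, lambdas, penalty)
        theta_o, cov_o = eq3_dense_oracle(blocks, basis, gamma, sigma2,
                                          lambdas, penalty)
        scale = np.abs(theta_o).max()
        np.testing.assert_allclose(theta, theta_o, atol=1e-8 * max(scale, 1))
        np.testing.assert_allclose(cov, cov_o, atol=1e-8)

    def test_huge_penalty_gives_affine_coefficient_function(self, rng):
        basis, blocks, _, _, _ = _random_instance(rng, n_subjects=12, n_cov=0)
        theta, _ = pgls_solve(blocks, basis, None, 1.0, np.array([1e10]))
        second_diff = np.diff(theta, n=2)
        assert np.abs(second_diff).max() < 1e-6

    def test_first_order_condition(self, rng):
        """sum X'V^-1 (y - X theta) = N P theta at the penalized optimum."""
        basis, blocks, gamma, sigma2, lambdas = _random_instance(rng)
        penalty = difference_penalty(basis.c)
        theta, _ = pgls_solve(blocks, basis, gamma, sigma2, lambdas, penalty)
        N = len(blocks)
        lhs = np.zeros_like(theta)
        for b in blocks:
            Bmat = b.X[:, : basis.c]
            V = Bmat @ gamma @ Bmat.T + sigma2 * np.eye(b.m)
            lhs += b.X.T @ np.linalg.solve(V, b.y - b.X @ theta)
        q = theta.size
        P = np.zeros((q, q))
        for p in range(q // basis.c):
            sl = slice(p * basis.c, (p + 1) * basis.c)
            P[sl, sl] = lambdas[p] * penalty.matrix
        np.testing.assert_allclose(lhs, N * P @ theta, atol=1e-6)

    def test_sandwich_reduces_to_single_bread_without_penalty(self, rng):
        basis, blocks, gamma, sigma2, _ = _random_instance(rng)
        theta, cov = pgls_solve(blocks, basis, gamma, sigma2, np.zeros(2))
        N = len(blocks)
        info = np.zeros((theta.size, theta.size))
        for b in blocks:
            Bmat = b.X[:, : basis.c]
            V = Bmat @ gamma @ Bmat.T + sigma2 * np.eye(b.m)
            info += b.X.T @ np.linalg.solve(V, b.X)
        np.testing.assert_allclose(cov, np.linalg.inv(info), atol=1e-8)


class TestSelectSmoothing:
    def test_pure_noise_selects_maximal_smoothing(self, rng):
        basis = build_basis(rng.uniform(size=100), n_interior=6)
        blocks = []
        for i in range(30):
            t = np.sort(rng.uniform(*basis.boundary, size=15))
            B = evaluate_basis(basis, t)
            blocks.append(DesignBlock(i, t, rng.normal(size=15), B,
                                      np.empty((15, 0))))
        lam = select_smoothing(blocks, basis, None, 1.0)
        # maximal smoothing: effective df collapses to the penalty null space
        penalty = difference_penalty(basis.c)
        XtX, _, _, _ = _whitened_crossproducts(blocks, basis, None, 1.0)
        edf = np.trace(
            np.linalg.solve(XtX + len(blocks) * lam[0] * penalty.matrix, XtX)
        )
        assert edf < penalty.order_of_difference + 0.5

    def test_noiseless_smooth_signal_selects_minimal_smoothing(self, rng):
        basis = build_basis(rng.uniform(size=100), n_interior=6)
        coefs = rng.normal(size=basis.c)
        blocks = []
        for i in range(30):
            t = np.sort(rng.uniform(*basis.boundary, size=15))
            B = evaluate_basis(basis, t)
            blocks.append(DesignBlock(i, t, B @ coefs, B, np.empty((15, 0))))
        lam = select_smoothing(blocks, basis, None, 1.0)
        assert lam[0] < 1e-2

    def test_reml_criterion_matches_direct_evaluation(self, rng):
        """Criterion values agree with an independent dense log-det formula."""
        basis, blocks, gamma, sigma2, _ = _random_instance(rng, n_subjects=6)
        penalty = difference_penalty(basis.c)
        XtX, Xty, yty, n = _whitened_crossproducts(blocks, basis, gamma, sigma2)
        N = len(blocks)
        q = XtX.shape[0]
        n_blocks = q // basis.c
        o = penalty.order_of_difference
        for lam_val in [1e-3, 1e-1, 1.0, 1e2, 1e4]:
            lams = np.full(n_blocks, lam_val)
            got = reml_criterion(lams, XtX, Xty, yty, n, N, penalty)
            # independent oracle built from stacked whitened matrices
            S = np.zeros((q, q))
            for p in range(n_blocks):
                sl = slice(p * basis.c, (p + 1) * basis.c)
                S[sl, sl] = N * lam_val * penalty.matrix
            M = XtX + S
            theta = np.linalg.solve(M, Xty)
            rss_pen = yty - theta @ Xty
            sign, logdet_m = np.linalg.slogdet(M)
            evs = np.linalg.eigvalsh(S)
            logdet_s = float(np.sum(np.log(evs[evs > 1e-8 * evs.max()])))
            n_eff = n - n_blocks * o
            expected = (
                n_eff * (1 + np.log(rss_pen / n_eff)) + logdet_m - logdet_s
            )
            assert abs(got - expected) < 1e-6 * max(abs(expected), 1.0)

    def test_effective_df_nonincreasing_in_lambda(self, rng):
        basis, blocks, gamma, sigma2, _ = _random_instance(rng, n_cov=0)
        penalty = difference_penalty(basis.c)
        XtX, _, _, _ = _whitened_crossproducts(blocks, basis, gamma, sigma2)
        edfs = []
        for lam in np.logspace(-6, 8, 15):
            M = XtX + lam * penalty.matrix
            edfs.append(np.trace(np.linalg.solve(M, XtX)))
        assert np.all(np.diff(edfs) <= 1e-8)


class TestFitFcr:
    def test_no_randomness_gives_null_variance_components(self):
        """With b_i = 0 and sigma_eps = 0 there is no randomness to find."""
        scenario = SimulationScenario(
            n_subjects=40, m_range=(10, 15), sigma_eps=0.0, n_test=1,
        )
        truth = scenario.truth
        truth.lambdas_b = np.zeros(5)
        truth.f[2] = lambda t: np.zeros_like(np.asarray(t, dtype=float))
        data = generate_dataset(scenario, 99)
        fit = fit_fcr(data.train, covariates=["male"])
        assert fit.sigma2_eps < 1e-4
        assert np.linalg.norm(fit.gamma) < 1e-3

    def test_second_variance_cycle_changes_little(self):
        """Extra variance-update iterations barely move the fitted functions."""
        scenario = SimulationScenario(n_subjects=100, m_range=(15, 25), n_test=1)
        data = generate_dataset(scenario, 5)
        fit1 = fit_fcr(data.train, covariates=["male"], tvc=["waz"], n_cycles=1)
        fit2 = fit_fcr(data.train, covariates=["male"], tvc=["waz"], n_cycles=2)
        t = np.linspace(*fit1.basis.boundary, 300)
        from fcreg import ise

        for p in range(3):
            est1, *_ = coefficient_function(fit1, p, t)
            est2, *_ = coefficient_function(fit2, p, t)
            scale = max(np.trapezoid(est1**2, t), 1e-12)
            assert ise(est1, est2, t) / scale < 0.01

    def test_coefficient_function_identity_covariance_propagation(
        self, small_dataset
    ):
        fit = fit_fcr(small_dataset.train, covariates=["male"], tvc=["waz"])
        c = fit.basis.c
        fit.cov_theta = np.eye(3 * c)
        t = np.linspace(*fit.basis.boundary, 50)
        _, se, lo, hi = coefficient_function(fit, 1, t)
        B = evaluate_basis(fit.basis, t)
        np.testing.assert_allclose(se**2, (B**2).sum(axis=1), atol=1e-10)
        np.testing.assert_allclose(hi - lo, 2 * 1.96 * se, atol=1e-10)

    def test_zero_coefficients_give_zero_function(self, small_dataset):
        fit = fit_fcr(small_dataset.train, covariates=["male"], tvc=["waz"])
        fit.theta = np.zeros_like(fit.theta)
        est, *_ = coefficient_function(fit, 2, np.linspace(*fit.basis.boundary, 20))
        np.testing.assert_array_equal(est, 0.0)

    def test_serialization_reproduces_predictions_bit_exactly(
        self, small_dataset, tmp_path
    ):
        from fcreg import FCRFit, predict_trajectory

        fit = fit_fcr(small_dataset.train, covariates=["male"], tvc=["waz"])
        path = tmp_path / "fit.json"
        fit.to_json(path)
        restored = FCRFit.from_json(path)
        subject = small_dataset.test[0]
        grid = np.linspace(0.5, fit.t_max, 20)
        p1 = predict_trajectory(fit, subject.restrict(0.5), grid)
        p2 = predict_trajectory(restored, subject.restrict(0.5), grid)
        np.testing.assert_array_equal(p1.y_hat, p2.y_hat)
        np.testing.assert_array_equal(p1.var, p2.var)
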