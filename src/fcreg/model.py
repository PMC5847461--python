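"""Functional concurrent regression by penalized generalized least squares.

The outcome model is

    Y_i(t) = f_0(t) + sum_p z_{p,i}(t) f_p(t) + b_i(t) + eps_i(t),

with smooth coefficient functions ``f_p``, a functional random intercept
``b_i`` (zero-mean Gaussian process with covariance ``C(s,t)``) and iid
Gaussian error.  All functions are expanded in a shared B-spline basis, so
the per-subject design is ``X_i = [B_i, diag(z_1i) B_i, ..., diag(z_Pi) B_i]``
and the stacked coefficient vector theta solves the penalized GLS problem

    theta = (N^-1 sum X_i' V_i^-1 X_i + P)^-1 N^-1 sum X_i' V_i^-1 y_i,

with ``V_i = B_i Gamma B_i' + sigma2 I`` and blockwise difference penalties
``P = blockdiag(lambda_p D'D)``.  Variance components (Gamma, sigma2) come
from a working-independence fit's residuals via sparse FPCA and are refined
once by default.  Error-contaminated time-varying covariates are replaced by
their BLUP reconstructions before entering the design.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import linalg, optimize

from .basis import (
    DEFAULT_NBASIS,
    DEFAULT_ORDER,
    DEFAULT_PENALTY_ORDER,
    PenaltyMatrix,
    SplineBasis,
    build_basis,
    difference_penalty,
    evaluate_basis,
)
from .containers import ObservedSubject
from .exceptions import (
    MissingDataError,
    RankDeficiencyError,
    SelectionError,
)
from .fpca import (
    LAMBDA_GRID,
    CovarianceModel,
    ObservedFunction,
    blup_curve,
    estimate_covariance,
    estimate_mean,
)

logger = logging.getLogger(__name__)

#: 95% pointwise confidence-interval multiplier for coefficient functions
CI_MULTIPLIER = 1.96


@dataclass
class DesignBlock:
    """Per-subject stacked design for the concurrent regression."""

    subject_id: object
    times: np.ndarray
    y: np.ndarray
    X: np.ndarray  # m x (P+1)c
    z: np.ndarray  # m x P covariate values entering the design

    @property
    def m(self) -> int:
        return self.times.size


@dataclass
class FCRFit:
    """Fitted functional concurrent regression model."""

    basis: SplineBasis
    theta: np.ndarray
    lambdas: np.ndarray
    random_model: CovarianceModel  # Gamma and sigma2_eps of the random intercept
    cov_theta: np.ndarray
    covariate_models: dict[str, CovarianceModel]
    block_names: list[str]
    tvc_names: list[str]
    n_subjects: int
    t_max: float
    penalty_order: int = DEFAULT_PENALTY_ORDER

    @property
    def n_blocks(self) -> int:
        return len(self.block_names)

    @property
    def sigma2_eps(self) -> float:
        return float(self.random_model.error_var)

    @property
    def gamma(self) -> np.ndarray:
        return self.random_model.gamma

    def theta_block(self, p: int) -> np.ndarray:
        c = self.basis.c
        return self.theta[p * c : (p + 1) * c]

    def to_json(self, path) -> None:
        d = {
            "type": "fcr",
            "basis": self.basis.to_dict(),
            "theta": self.theta.tolist(),
            "lambdas": self.lambdas.tolist(),
            "random_model": self.random_model.to_dict(),
            "cov_theta": self.cov_theta.tolist(),
            "covariate_models": {
                k: v.to_dict() for k, v in self.covariate_models.items()
            },
            "block_names": list(self.block_names),
            "tvc_names": list(self.tvc_names),
            "n_subjects": int(self.n_subjects),
            "t_max": float(self.t_max),
            "penalty_order": int(self.penalty_order),
        }
        with open(path, "w") as fh:
            json.dump(d, fh)

    @classmethod
    def from_json(cls, path) -> "FCRFit":
        with open(path) as fh:
            d = json.load(fh)
        return cls.from_dict(d)

    @classmethod
    def from_dict(cls, d: dict) -> "FCRFit":
        return cls(
            basis=SplineBasis.from_dict(d["basis"]),
            theta=np.asarray(d["theta"], dtype=float),
            lambdas=np.asarray(d["lambdas"], dtype=float),
            random_model=CovarianceModel.from_dict(d["random_model"]),
            cov_theta=np.asarray(d["cov_theta"], dtype=float),
            covariate_models={
                k: CovarianceModel.from_dict(v)
                for k, v in d["covariate_models"].items()
            },
            block_names=list(d["block_names"]),
            tvc_names=list(d["tvc_names"]),
            n_subjects=int(d["n_subjects"]),
            t_max=float(d["t_max"]),
            penalty_order=int(d["penalty_order"]),
        )


# ---------------------------------------------------------------------------
# design assembly
# ---------------------------------------------------------------------------

def fit_covariate_models(
    data: list[ObservedSubject],
    tvc: list[str],
    basis: SplineBasis,
    penalty: PenaltyMatrix | None = None,
) -> dict[str, CovarianceModel]:
    """Sparse-FPCA models (mean, covariance, nugget) for each time-varying covariate."""
    models: dict[str, CovarianceModel] = {}
    for name in tvc:
        funcs = []
        for s in data:
            if name not in s.tvc:
                raise MissingDataError(f"subject {s.subject_id} lacks covariate {name}")
            vals = s.tvc[name]
            ok = np.isfinite(vals)
            if ok.any():
                funcs.append(ObservedFunction(s.times[ok], vals[ok]))
        mean = estimate_mean(funcs, basis, penalty)
        models[name] = estimate_covariance(funcs, mean, basis, penalty)
    return models


def assemble_design(
    data: list[ObservedSubject],
    basis: SplineBasis,
    covariates: list[str] = (),
    tvc: list[str] = (),
    covariate_models: dict[str, CovarianceModel] | None = None,
    use_blup: bool = True,
) -> list[DesignBlock]:
    """Build per-subject design matrices, denoising time-varying covariates.

    Time-invariant covariates are broadcast across visits; each time-varying
    covariate is replaced by its BLUP reconstruction at the outcome's visit
    times, conditional on the subject's own noisy covariate observations.
    With ``use_blup=False`` the raw observed covariate values enter the
    design instead (how the simpler comparison models are usually fit).
    """
    covariate_models = covariate_models or {}
    for name in tvc:
        if use_blup and name not in covariate_models:
            raise MissingDataError(f"no covariate model supplied for '{name}'")
    blocks = []
    for s in data:
        B = evaluate_basis(basis, s.times)
        cols = [B]
        zs = []
        for name in covariates:
            if name not in s.covariates:
                raise MissingDataError(
                    f"subject {s.subject_id} lacks covariate {name}"
                )
            z = np.full(s.m, float(s.covariates[name]))
            zs.append(z)
            cols.append(z[:, None] * B)
        for name in tvc:
            vals = s.tvc.get(name)
            if vals is None:
                raise MissingDataError(f"subject {s.subject_id} lacks covariate {name}")
            if use_blup:
                ok = np.isfinite(vals)
                obs = ObservedFunction(s.times[ok], vals[ok]) if ok.any() else None
                z, _ = blup_curve(covariate_models[name], obs, s.times)
            else:
                if not np.isfinite(vals).all():
                    raise MissingDataError(
                        f"subject {s.subject_id} has missing '{name}' values and "
                        "no covariate model for imputation"
                    )
                z = np.asarray(vals, dtype=float)
            zs.append(z)
            cols.append(z[:, None] * B)
        blocks.append(
            DesignBlock(
                subject_id=s.subject_id,
                times=s.times,
                y=s.y,
                X=np.hstack(cols),
                z=np.column_stack(zs) if zs else np.empty((s.m, 0)),
            )
        )
    return blocks


# ---------------------------------------------------------------------------
# penalized GLS
# ---------------------------------------------------------------------------

def _subject_vinv(
    block: DesignBlock,
    basis: SplineBasis,
    gamma: np.ndarray | None,
    sigma2: float,
) -> np.ndarray:
    """V_i^{-1} with V_i = B_i Gamma B_i' + sigma2 I (Cholesky with jitter)."""
    m = block.m
    if gamma is None:
        return np.eye(m) / sigma2
    B = block.X[:, : basis.c]
    V = B @ gamma @ B.T + sigma2 * np.eye(m)
    jitter = 0.0
    for _ in range(4):
        try:
            cf = linalg.cho_factor(V + jitter * np.eye(m))
            return linalg.cho_solve(cf, np.eye(m))
        except linalg.LinAlgError:
            jitter = max(jitter * 10, 1e-8 * np.trace(V) / m)
    raise RankDeficiencyError(f"subject {block.subject_id}: V_i not invertible")


def _penalty_blockdiag(lambdas: np.ndarray, penalty: PenaltyMatrix, n_blocks: int):
    mats = [lambdas[p] * penalty.matrix for p in range(n_blocks)]
    return linalg.block_diag(*mats)


def pgls_solve(
    blocks: list[DesignBlock],
    basis: SplineBasis,
    gamma: np.ndarray | None,
    sigma2: float,
    lambdas: np.ndarray,
    penalty: PenaltyMatrix | None = None,
    vinvs: list[np.ndarray] | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Penalized GLS estimate of theta and its sandwich covariance.

    Solves ``theta = (N^-1 sum X'V^-1 X + P)^-1 N^-1 sum X'V^-1 y`` and
    computes ``Cov(theta) = A^-1 (N^-2 sum X'V^-1 X) A^-1`` with
    ``A`` the penalized information matrix (same V throughout).  ``vinvs``
    overrides the default random-intercept working covariance (used by
    competitor models with other random-effect structures).
    """
    if penalty is None:
        penalty = difference_penalty(basis.c)
    N = len(blocks)
    q = blocks[0].X.shape[1]
    n_blocks = q // basis.c
    G = np.zeros((q, q))
    g = np.zeros(q)
    for i, b in enumerate(blocks):
        Vinv = vinvs[i] if vinvs is not None else _subject_vinv(b, basis, gamma, sigma2)
        XtVi = b.X.T @ Vinv
        G += XtVi @ b.X
        g += XtVi @ b.y
    P = _penalty_blockdiag(np.asarray(lambdas, dtype=float), penalty, n_blocks)
    A = G / N + P
    try:
        cf = linalg.cho_factor(A)
    except linalg.LinAlgError as exc:
        c = basis.c
        for p in range(n_blocks):
            sub = A[p * c : (p + 1) * c, p * c : (p + 1) * c]
            if np.linalg.eigvalsh(sub).min() <= 0:
                raise RankDeficiencyError(
                    f"penalized information singular in block {p}"
                ) from exc
        raise RankDeficiencyError("penalized information matrix singular") from exc
    theta = linalg.cho_solve(cf, g / N)
    A_inv = linalg.cho_solve(cf, np.eye(q))
    cov_theta = A_inv @ (G / N**2) @ A_inv
    cov_theta = 0.5 * (cov_theta + cov_theta.T)
    return theta, cov_theta


# ---------------------------------------------------------------------------
# smoothing-parameter selection
# ---------------------------------------------------------------------------

def _whitened_crossproducts(
    blocks: list[DesignBlock],
    basis: SplineBasis,
    gamma: np.ndarray | None,
    sigma2: float,
    vinvs: list[np.ndarray] | None = None,
) -> tuple[np.ndarray, np.ndarray, float, int]:
    q = blocks[0].X.shape[1]
    XtX = np.zeros((q, q))
    Xty = np.zeros(q)
    yty = 0.0
    n = 0
    for i, b in enumerate(blocks):
        Vinv = vinvs[i] if vinvs is not None else _subject_vinv(b, basis, gamma, sigma2)
        XtVi = b.X.T @ Vinv
        XtX += XtVi @ b.X
        Xty += XtVi @ b.y
        yty += float(b.y @ Vinv @ b.y)
        n += b.m
    return XtX, Xty, yty, n


def reml_criterion(
    lambdas: np.ndarray,
    XtX: np.ndarray,
    Xty: np.ndarray,
    yty: float,
    n: int,
    N: int,
    penalty: PenaltyMatrix,
) -> float:
    """-2 x restricted log-likelihood (up to an additive constant).

    Treats the penalty as a Gaussian prior on the spline coefficients in the
    V-whitened regression, with the residual scale profiled out over the
    ``n - p0`` penalized degrees of freedom (``p0`` = total null-space dim).
    """
    q = XtX.shape[0]
    c = penalty.c
    n_blocks = q // c
    o = penalty.order_of_difference
    S = _penalty_blockdiag(N * np.asarray(lambdas, dtype=float), penalty, n_blocks)
    M = XtX + S
    try:
        cf = linalg.cho_factor(M)
    except linalg.LinAlgError:
        return np.inf
    theta = linalg.cho_solve(cf, Xty)
    rss_pen = max(yty - float(theta @ Xty), 1e-300)
    logdet_M = 2.0 * float(np.sum(np.log(np.diag(cf[0]))))
    # pseudo-determinant of S: (c-o) positive eigenvalues per block scale with
    # N*lambda_p; the D'D spectrum contributes a lambda-independent constant
    pos = np.linalg.eigvalsh(penalty.matrix)[o:]
    logdet_S = float(
        np.sum((c - o) * np.log(N * np.asarray(lambdas, dtype=float)))
        + n_blocks * np.sum(np.log(pos))
    )
    n_eff = n - n_blocks * o
    return n_eff * (1.0 + np.log(rss_pen / n_eff)) + logdet_M - logdet_S


def gcv_criterion(
    lambdas: np.ndarray,
    XtX: np.ndarray,
    Xty: np.ndarray,
    yty: float,
    n: int,
    N: int,
    penalty: PenaltyMatrix,
) -> float:
    """Generalized cross-validation score of the whitened penalized regression."""
    q = XtX.shape[0]
    n_blocks = q // penalty.c
    S = _penalty_blockdiag(N * np.asarray(lambdas, dtype=float), penalty, n_blocks)
    M = XtX + S
    try:
        cf = linalg.cho_factor(M)
    except linalg.LinAlgError:
        return np.inf
    theta = linalg.cho_solve(cf, Xty)
    edf = float(np.trace(linalg.cho_solve(cf, XtX)))
    rss = max(yty - 2.0 * float(theta @ Xty) + float(theta @ XtX @ theta), 0.0)
    denom = max(n - edf, 1e-10)
    return n * rss / denom**2


def select_smoothing(
    blocks: list[DesignBlock],
    basis: SplineBasis,
    gamma: np.ndarray | None,
    sigma2: float,
    penalty: PenaltyMatrix | None = None,
    method: str = "reml",
    grid: np.ndarray = LAMBDA_GRID,
    n_sweeps: int = 2,
    vinvs: list[np.ndarray] | None = None,
) -> np.ndarray:
    """Per-block smoothing parameters by coordinate descent on a log grid.

    Each block's lambda is optimized in turn on ``grid`` and refined by
    bounded golden-section search on the log scale; the default criterion is
    REML of the whitened penalized regression, with GCV as an option.
    """
    if penalty is None:
        penalty = difference_penalty(basis.c)
    crit_fn = {"reml": reml_criterion, "gcv": gcv_criterion}[method]
    XtX, Xty, yty, n = _whitened_crossproducts(blocks, basis, gamma, sigma2, vinvs)
    N = len(blocks)
    q = XtX.shape[0]
    n_blocks = q // basis.c
    lambdas = np.ones(n_blocks)

    def crit(lams):
        return crit_fn(lams, XtX, Xty, yty, n, N, penalty)

    any_finite = False
    for _ in range(n_sweeps):
        for p in range(n_blocks):
            vals = []
            for lam in grid:
                trial = lambdas.copy()
                trial[p] = lam
                vals.append(crit(trial))
            vals = np.asarray(vals)
            if not np.any(np.isfinite(vals)):
                continue
            any_finite = True
            k = int(np.nanargmin(vals))
            lo = np.log(grid[max(k - 1, 0)])
            hi = np.log(grid[min(k + 1, grid.size - 1)])
            if hi > lo:
                def f(loglam, p=p):
                    trial = lambdas.copy()
                    trial[p] = np.exp(loglam)
                    return crit(trial)

                res = optimize.minimize_scalar(
                    f, bounds=(lo, hi), method="bounded",
                    options={"xatol": 1e-2},
                )
                lambdas[p] = (
                    np.exp(res.x) if res.fun <= vals[k] else grid[k]
                )
            else:
                lambdas[p] = grid[k]
    if not any_finite:
        raise SelectionError("smoothing criterion non-finite across the grid")
    return lambdas


# ---------------------------------------------------------------------------
# the full 4-step fitting procedure
# ---------------------------------------------------------------------------

def fit_fcr(
    data: list[ObservedSubject],
    covariates: list[str] = (),
    tvc: list[str] = (),
    basis: SplineBasis | None = None,
    n_basis: int = DEFAULT_NBASIS,
    order: int = DEFAULT_ORDER,
    penalty_order: int = DEFAULT_PENALTY_ORDER,
    selector: str = "reml",
    n_cycles: int = 1,
    covariate_models: dict[str, CovarianceModel] | None = None,
) -> FCRFit:
    """Fit the functional concurrent regression model.

    Variance components are estimated by the iterative procedure: (1) a
    working-independence penalized GLS fit; (2) sparse-FPCA covariance
    estimation on its residuals, yielding (Gamma, sigma2); (3) a GLS refit
    with the estimated V_i; (4) covariance re-estimation from the refreshed
    residuals.  Smoothing parameters are reselected at each GLS step.
    ``n_cycles`` extra repetitions of steps 3-4 are available but one cycle
    changes little in practice.
    """
    if not data:
        raise ValueError("no subjects supplied")
    covariates = list(covariates)
    tvc = list(tvc)
    all_times = np.concatenate([s.times for s in data])
    if basis is None:
        basis = build_basis(all_times, n_interior=n_basis - order, order=order)
    penalty = difference_penalty(basis.c, penalty_order)
    if covariate_models is None:
        covariate_models = fit_covariate_models(data, tvc, basis, penalty)
    blocks = assemble_design(data, basis, covariates, tvc, covariate_models)

    # step 1: working independence
    lambdas = select_smoothing(blocks, basis, None, 1.0, penalty, selector)
    theta, cov_theta = pgls_solve(blocks, basis, None, 1.0, lambdas, penalty)

    random_model = None
    for cycle in range(max(n_cycles, 1)):
        # step 2/4: covariance of the functional random intercept from residuals
        resid = [
            ObservedFunction(b.times, b.y - b.X @ theta) for b in blocks
        ]
        random_model = estimate_covariance(
            resid, np.zeros(basis.c), basis, penalty
        )
        # step 3: GLS refit under the estimated V_i
        lambdas = select_smoothing(
            blocks, basis, random_model.gamma, random_model.error_var, penalty,
            selector,
        )
        theta, cov_theta = pgls_solve(
            blocks, basis, random_model.gamma, random_model.error_var, lambdas,
            penalty,
        )
    # final re-estimate of the variance components (step 4)
    resid = [ObservedFunction(b.times, b.y - b.X @ theta) for b in blocks]
    random_model = estimate_covariance(resid, np.zeros(basis.c), basis, penalty)

    return FCRFit(
        basis=basis,
        theta=theta,
        lambdas=lambdas,
        random_model=random_model,
        cov_theta=cov_theta,
        covariate_models=covariate_models,
        block_names=["intercept"] + covariates + tvc,
        tvc_names=tvc,
        n_subjects=len(data),
        t_max=float(all_times.max()),
        penalty_order=penalty_order,
    )


def coefficient_function(
    fit: FCRFit, p: int | str, t: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Evaluate a fitted coefficient function with pointwise SEs and 95% CI.

    Returns ``(estimate, se, lo95, hi95)`` where the SE propagates the block
    of the sandwich covariance: ``se(t)^2 = B(t)' Cov(theta_p) B(t)``.
    """
    if isinstance(p, str):
        p = fit.block_names.index(p)
    if not 0 <= p < len(fit.block_names):
        raise IndexError(f"coefficient index {p} out of range")
    c = fit.basis.c
    B = evaluate_basis(fit.basis, t)
    est = B @ fit.theta[p * c : (p + 1) * c]
    cov_p = fit.cov_theta[p * c : (p + 1) * c, p * c : (p + 1) * c]
    se = np.sqrt(np.maximum(np.einsum("ij,jk,ik->i", B, cov_p, B), 0.0))
    return est, se, est - CI_MULTIPLIER * se, est + CI_MULTIPLIER * se


def coefficient_table(fit: FCRFit, p: int | str, t: np.ndarray) -> pd.DataFrame:
    """Tidy (t, estimate, se, lo95, hi95) export of a coefficient function."""
    est, se, lo, hi = coefficient_function(fit, p, t)
    return pd.DataFrame(
        {"t": np.asarray(t, dtype=float), "estimate": est, "se": se,
         "lo95": lo, "hi95": hi}
    )
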