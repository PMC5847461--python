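"""Comparison models: AM, AMM and FRI.

Three simpler models sharing the FCR mean structure or random structure:

* AM  -- the additive model: same time-varying coefficient functions but no
  subject random effects (``V_i = sigma2 I``).
* AMM -- additive mixed model: same mean structure plus a scalar random
  intercept and slope, ``b_0i + b_1i t``, with unstructured bivariate normal
  covariance Psi estimated by REML.
* FRI -- functional random intercept only: the FCR machinery with the
  covariate list empty.

Each has a dynamic-prediction counterpart so the models can be benchmarked
head-to-head on out-of-sample trajectory prediction.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass

import numpy as np
from scipy import linalg, optimize

from .basis import (
    DEFAULT_NBASIS,
    DEFAULT_ORDER,
    DEFAULT_PENALTY_ORDER,
    SplineBasis,
    build_basis,
    difference_penalty,
)
from .containers import ObservedSubject
from .fpca import CovarianceModel, project_psd
from .model import (
    DesignBlock,
    FCRFit,
    _penalty_blockdiag,
    _whitened_crossproducts,
    assemble_design,
    fit_covariate_models,
    fit_fcr,
    pgls_solve,
    select_smoothing,
)
from .predict import (
    PREDICTION_MULTIPLIER,
    PredictionResult,
    _check_grid,
    _fixed_part,
)

logger = logging.getLogger(__name__)


@dataclass
class AMMFit:
    """Additive mixed model fit: random intercept + slope per subject."""

    basis: SplineBasis
    theta: np.ndarray
    lambdas: np.ndarray
    psi: np.ndarray  # 2x2 covariance of (b_0i, b_1i)
    sigma2_eps: float
    cov_theta: np.ndarray
    covariate_models: dict[str, CovarianceModel]
    block_names: list[str]
    tvc_names: list[str]
    n_subjects: int
    t_max: float
    penalty_order: int = DEFAULT_PENALTY_ORDER

    @property
    def correlation(self) -> float:
        d = np.sqrt(np.diag(self.psi))
        if np.all(d > 0):
            return float(self.psi[0, 1] / (d[0] * d[1]))
        return 0.0

    def to_json(self, path) -> None:
        d = {
            "type": "amm",
            "basis": self.basis.to_dict(),
            "theta": self.theta.tolist(),
            "lambdas": self.lambdas.tolist(),
            "psi": self.psi.tolist(),
            "sigma2_eps": float(self.sigma2_eps),
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
    def from_dict(cls, d: dict) -> "AMMFit":
        return cls(
            basis=SplineBasis.from_dict(d["basis"]),
            theta=np.asarray(d["theta"], dtype=float),
            lambdas=np.asarray(d["lambdas"], dtype=float),
            psi=np.asarray(d["psi"], dtype=float),
            sigma2_eps=float(d["sigma2_eps"]),
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
# AM: no random effects
# ---------------------------------------------------------------------------

def fit_am(
    data: list[ObservedSubject],
    covariates: list[str] = (),
    tvc: list[str] = (),
    basis: SplineBasis | None = None,
    n_basis: int = DEFAULT_NBASIS,
    order: int = DEFAULT_ORDER,
    penalty_order: int = DEFAULT_PENALTY_ORDER,
    selector: str = "reml",
    covariate_models: dict[str, CovarianceModel] | None = None,
) -> FCRFit:
    """Additive model: FCR mean structure with ``V_i = sigma2 I`` (Gamma = 0).

    The residual variance uses an effective-degrees-of-freedom correction,
    ``sigma2 = RSS / (n - edf)``.
    """
    covariates = list(covariates)
    tvc = list(tvc)
    all_times = np.concatenate([s.times for s in data])
    if basis is None:
        basis = build_basis(all_times, n_interior=n_basis - order, order=order)
    penalty = difference_penalty(basis.c, penalty_order)
    # the additive model is fit on the raw observed covariate values; a
    # covariate model is kept only if supplied (e.g. for later prediction)
    covariate_models = covariate_models or {}
    blocks = assemble_design(
        data, basis, covariates, tvc, covariate_models, use_blup=False
    )

    lambdas = select_smoothing(blocks, basis, None, 1.0, penalty, selector)
    theta, _ = pgls_solve(blocks, basis, None, 1.0, lambdas, penalty)
    sigma2 = _residual_variance(blocks, basis, theta, lambdas, penalty)
    # refit under the estimated iid variance so the sandwich has proper scale
    lambdas = select_smoothing(blocks, basis, None, sigma2, penalty, selector)
    theta, cov_theta = pgls_solve(blocks, basis, None, sigma2, lambdas, penalty)
    sigma2 = _residual_variance(blocks, basis, theta, lambdas, penalty)

    c = basis.c
    random_model = CovarianceModel(
        basis=basis,
        mean_coeffs=np.zeros(c),
        gamma=np.zeros((c, c)),
        error_var=sigma2,
        eigenvalues=np.zeros(1),
        eigenfunction_coeffs=np.zeros((c, 1)),
    )
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


def _residual_variance(blocks, basis, theta, lambdas, penalty) -> float:
    XtX, Xty, yty, n = _whitened_crossproducts(blocks, basis, None, 1.0)
    N = len(blocks)
    S = _penalty_blockdiag(N * np.asarray(lambdas), penalty, XtX.shape[0] // basis.c)
    edf = float(np.trace(linalg.solve(XtX + S, XtX)))
    rss = sum(float(np.sum((b.y - b.X @ theta) ** 2)) for b in blocks)
    return rss / max(n - edf, 1.0)


# ---------------------------------------------------------------------------
# AMM: scalar random intercept + slope
# ---------------------------------------------------------------------------

def _amm_subject_stats(blocks: list[DesignBlock]) -> list[dict]:
    stats = []
    for b in blocks:
        Z = np.column_stack([np.ones(b.m), b.times])
        stats.append(
            {
                "XtX": b.X.T @ b.X,
                "Xty": b.X.T @ b.y,
                "yty": float(b.y @ b.y),
                "XtZ": b.X.T @ Z,
                "Zty": Z.T @ b.y,
                "ZtZ": Z.T @ Z,
                "m": b.m,
            }
        )
    return stats


def _psi_from_params(x: np.ndarray) -> tuple[float, np.ndarray]:
    sigma2 = np.exp(x[0])
    d1, d2 = np.exp(x[1]), np.exp(x[2])
    rho = np.tanh(x[3])
    psi = np.array(
        [[d1, rho * np.sqrt(d1 * d2)], [rho * np.sqrt(d1 * d2), d2]]
    )
    return float(sigma2), psi


def amm_neg2_reml(
    stats: list[dict],
    psi: np.ndarray,
    sigma2: float,
    S: np.ndarray,
) -> float:
    """-2 restricted log-likelihood of the AMM (up to a constant).

    ``sum_i log|V_i| + log|sum_i X'V^-1 X + S| + min_theta (penalized
    weighted RSS)`` with ``V_i = sigma2 I + Z_i Psi Z_i'`` and fixed
    penalty ``S``; evaluated with the Woodbury identity on the 2x2 core.
    """
    q = S.shape[0]
    XtX_w = np.zeros((q, q))
    Xty_w = np.zeros(q)
    yty_w = 0.0
    logdet_v = 0.0
    try:
        psi_inv = linalg.inv(psi)
    except linalg.LinAlgError:
        return np.inf
    for s in stats:
        core = sigma2 * psi_inv + s["ZtZ"]
        try:
            core_inv = linalg.inv(core)
        except linalg.LinAlgError:
            return np.inf
        sign, ld_core = np.linalg.slogdet(np.eye(2) + psi @ s["ZtZ"] / sigma2)
        if sign <= 0:
            return np.inf
        logdet_v += s["m"] * np.log(sigma2) + ld_core
        XtX_w += (s["XtX"] - s["XtZ"] @ core_inv @ s["XtZ"].T) / sigma2
        Xty_w += (s["Xty"] - s["XtZ"] @ core_inv @ s["Zty"]) / sigma2
        yty_w += (s["yty"] - float(s["Zty"] @ core_inv @ s["Zty"])) / sigma2
    M = XtX_w + S
    try:
        cf = linalg.cho_factor(M)
    except linalg.LinAlgError:
        return np.inf
    theta = linalg.cho_solve(cf, Xty_w)
    rss_pen = yty_w - float(theta @ Xty_w)
    logdet_m = 2.0 * float(np.sum(np.log(np.diag(cf[0]))))
    return logdet_v + logdet_m + rss_pen


def fit_amm(
    data: list[ObservedSubject],
    covariates: list[str] = (),
    tvc: list[str] = (),
    basis: SplineBasis | None = None,
    n_basis: int = DEFAULT_NBASIS,
    order: int = DEFAULT_ORDER,
    penalty_order: int = DEFAULT_PENALTY_ORDER,
    selector: str = "reml",
    covariate_models: dict[str, CovarianceModel] | None = None,
    maxiter: int = 200,
) -> AMMFit:
    """Additive mixed model with random intercept + slope, fit by REML.

    Variance components (2x2 Psi and sigma2) maximize the restricted
    likelihood via Nelder-Mead on an unconstrained parameterization
    (log variances, atanh correlation), started from per-subject line fits;
    fixed effects are then re-estimated by penalized GLS under ``V_i =
    Z_i Psi Z_i' + sigma2 I``.
    """
    covariates = list(covariates)
    tvc = list(tvc)
    all_times = np.concatenate([s.times for s in data])
    if basis is None:
        basis = build_basis(all_times, n_interior=n_basis - order, order=order)
    penalty = difference_penalty(basis.c, penalty_order)
    # design uses raw observed covariates (errors-in-variables and all, as
    # these models are conventionally fit); the covariate model is retained
    # for dynamic prediction, where future covariate values need a BLUP
    if covariate_models is None and tvc:
        covariate_models = fit_covariate_models(data, tvc, basis, penalty)
    covariate_models = covariate_models or {}
    blocks = assemble_design(
        data, basis, covariates, tvc, covariate_models, use_blup=False
    )
    N = len(blocks)
    n_blocks = blocks[0].X.shape[1] // basis.c

    # working-independence start
    lambdas = select_smoothing(blocks, basis, None, 1.0, penalty, selector)
    theta0, _ = pgls_solve(blocks, basis, None, 1.0, lambdas, penalty)

    # moment starting values from per-subject line fits on residuals
    coefs, ssr, nresid = [], 0.0, 0
    for b in blocks:
        e = b.y - b.X @ theta0
        Z = np.column_stack([np.ones(b.m), b.times])
        if b.m >= 3:
            beta, res, *_ = np.linalg.lstsq(Z, e, rcond=None)
            coefs.append(beta)
            if res.size:
                ssr += float(res[0])
                nresid += b.m - 2
    coefs = np.asarray(coefs)
    psi0 = project_psd(np.cov(coefs.T)) if len(coefs) >= 2 else np.eye(2)
    sigma2_0 = ssr / max(nresid, 1) if nresid else 1.0
    d0 = np.maximum(np.diag(psi0), 1e-6)
    rho0 = np.clip(psi0[0, 1] / np.sqrt(d0[0] * d0[1]), -0.95, 0.95)
    x0 = np.array(
        [np.log(max(sigma2_0, 1e-8)), np.log(d0[0]), np.log(d0[1]),
         np.arctanh(rho0)]
    )

    stats = _amm_subject_stats(blocks)
    S = _penalty_blockdiag(N * lambdas, penalty, n_blocks)

    def objective(x):
        if np.any(np.abs(x) > 30):
            return np.inf
        sigma2, psi = _psi_from_params(x)
        return amm_neg2_reml(stats, psi, sigma2, S)

    res = optimize.minimize(
        x0=x0, fun=objective, method="Nelder-Mead",
        options={"maxiter": maxiter, "fatol": 1e-4, "xatol": 1e-3},
    )
    if not res.success:
        logger.warning("AMM REML optimisation did not fully converge: %s", res.message)
    sigma2, psi = _psi_from_params(res.x)
    psi = project_psd(psi)

    vinvs = _amm_vinvs(blocks, psi, sigma2)
    lambdas = select_smoothing(
        blocks, basis, None, sigma2, penalty, selector, vinvs=vinvs
    )
    theta, cov_theta = pgls_solve(
        blocks, basis, None, sigma2, lambdas, penalty, vinvs=vinvs
    )
    return AMMFit(
        basis=basis,
        theta=theta,
        lambdas=lambdas,
        psi=psi,
        sigma2_eps=sigma2,
        cov_theta=cov_theta,
        covariate_models=covariate_models,
        block_names=["intercept"] + covariates + tvc,
        tvc_names=tvc,
        n_subjects=N,
        t_max=float(all_times.max()),
        penalty_order=penalty_order,
    )


def _amm_vinvs(blocks, psi, sigma2) -> list[np.ndarray]:
    out = []
    for b in blocks:
        Z = np.column_stack([np.ones(b.m), b.times])
        V = Z @ psi @ Z.T + sigma2 * np.eye(b.m)
        out.append(linalg.inv(V))
    return out


# ---------------------------------------------------------------------------
# FRI: functional random intercept, no covariates
# ---------------------------------------------------------------------------

def fit_fri(data: list[ObservedSubject], **kwargs) -> FCRFit:
    """Functional-random-intercept model: the FCR fit with no covariates."""
    kwargs.pop("covariates", None)
    kwargs.pop("tvc", None)
    return fit_fcr(data, covariates=(), tvc=(), **kwargs)


# ---------------------------------------------------------------------------
# AMM dynamic prediction
# ---------------------------------------------------------------------------

def predict_amm(
    fit: AMMFit,
    history: ObservedSubject | None,
    t_grid: np.ndarray,
    future_covariates: dict[str, np.ndarray] | None = None,
) -> PredictionResult:
    """BLUP dynamic prediction under the random intercept + slope model.

    The subject's (b_0, b_1) are predicted by Gaussian conditioning on the
    history; the trajectory is the fixed part plus ``b~_0 + b~_1 t`` with
    pointwise variance ``[1,t] Psi_post [1,t]' + sigma2``.
    """
    t_grid = _check_grid(t_grid, fit.t_max)
    psi, sigma2 = fit.psi, fit.sigma2_eps
    if history is None:
        history = ObservedSubject(subject_id=None, times=[], y=[])
    if history.m > 0:
        X_hist, fixed_hist = _fixed_part(fit, history, history.times)
        Z = np.column_stack([np.ones(history.m), history.times])
        K = Z @ psi @ Z.T + sigma2 * np.eye(history.m)
        resid = history.y - fixed_hist
        b_tilde = psi @ Z.T @ linalg.solve(K, resid, assume_a="pos")
        psi_post = psi - psi @ Z.T @ linalg.solve(K, Z @ psi, assume_a="pos")
        cutoff = float(history.times.max())
    else:
        b_tilde = np.zeros(2)
        psi_post = psi
        cutoff = -np.inf
    _, fixed_grid = _fixed_part(fit, history, t_grid, future_covariates)
    Zg = np.column_stack([np.ones(t_grid.size), t_grid])
    y_hat = fixed_grid + Zg @ b_tilde
    var = np.einsum("ij,jk,ik->i", Zg, psi_post, Zg) + sigma2
    var = np.maximum(var, 0.0)
    sd = np.sqrt(var)
    return PredictionResult(
        t_grid=t_grid,
        y_hat=y_hat,
        u_tilde=b_tilde,
        var=var,
        lo95=y_hat - PREDICTION_MULTIPLIER * sd,
        hi95=y_hat + PREDICTION_MULTIPLIER * sd,
        t_max=fit.t_max,
        conditioning_cutoff=cutoff,
    )
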