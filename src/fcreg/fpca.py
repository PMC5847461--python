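"""Sparse functional principal component analysis.

Mean, smooth covariance surface, eigenstructure and nugget (error) variance
for a functional variable observed at few, irregular, noisy points per
subject.  The covariance surface is expanded on a tensor-product B-spline
basis, ``C(s,t) = sum_{k,l} gamma_kl B_k(s) B_l(t)``, and estimated by
penalized regression of off-diagonal residual cross-products, followed by
projection onto the positive-semidefinite cone.  Conditional-expectation
(BLUP) curve reconstruction then follows from Gaussian conditioning:

    Z~(t) = mu(t) + C(t, t_i)' [C(t_i, t_i) + sigma2 I]^{-1} (Z_obs - mu(t_i)).

This machinery is used twice in the concurrent regression pipeline: to
denoise the error-contaminated time-varying covariate, and to estimate the
covariance of the outcome's functional random intercept from residuals.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg

from .basis import (
    PenaltyMatrix,
    SplineBasis,
    difference_penalty,
    evaluate_basis,
    gram_matrix,
)
from .exceptions import (
    IdentifiabilityError,
    RankDeficiencyError,
    SingularityError,
)

#: log10-spaced smoothing-parameter grid used by GCV selection
LAMBDA_GRID = np.logspace(-6, 8, 29)
#: cumulative eigenvalue share kept when truncating the eigen-decomposition
EIGEN_SHARE = 0.9999


@dataclass
class ObservedFunction:
    """One subject's sparse observations of a functional variable."""

    times: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float).ravel()
        v = np.asarray(self.values, dtype=float).ravel()
        if t.size != v.size:
            raise ValueError("times and values must have equal length")
        order = np.argsort(t, kind="stable")
        self.times = t[order]
        self.values = v[order]

    @property
    def m(self) -> int:
        return self.times.size


@dataclass
class CovarianceModel:
    """Mean + covariance model for a sparsely observed functional variable.

    ``C(s,t) = sum_{k,l} gamma_kl B_k(s) B_l(t)`` with nugget ``error_var``;
    ``eigenvalues``/``eigenfunction_coeffs`` hold the L2-orthonormal
    eigenpairs of the integral operator with kernel ``C``.
    """

    basis: SplineBasis
    mean_coeffs: np.ndarray
    gamma: np.ndarray
    error_var: float
    eigenvalues: np.ndarray = field(default_factory=lambda: np.empty(0))
    eigenfunction_coeffs: np.ndarray = field(default_factory=lambda: np.empty((0, 0)))

    def mean_at(self, t: np.ndarray) -> np.ndarray:
        return evaluate_basis(self.basis, t) @ self.mean_coeffs

    def cov_between(self, s: np.ndarray, t: np.ndarray) -> np.ndarray:
        Bs = evaluate_basis(self.basis, s)
        Bt = evaluate_basis(self.basis, t)
        return Bs @ self.gamma @ Bt.T

    def var_at(self, t: np.ndarray) -> np.ndarray:
        B = evaluate_basis(self.basis, t)
        return np.einsum("ij,jk,ik->i", B, self.gamma, B)

    def to_dict(self) -> dict:
        return {
            "basis": self.basis.to_dict(),
            "mean_coeffs": self.mean_coeffs.tolist(),
            "gamma": self.gamma.tolist(),
            "error_var": float(self.error_var),
            "eigenvalues": self.eigenvalues.tolist(),
            "eigenfunction_coeffs": np.asarray(self.eigenfunction_coeffs).tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CovarianceModel":
        return cls(
            basis=SplineBasis.from_dict(d["basis"]),
            mean_coeffs=np.asarray(d["mean_coeffs"], dtype=float),
            gamma=np.asarray(d["gamma"], dtype=float),
            error_var=float(d["error_var"]),
            eigenvalues=np.asarray(d["eigenvalues"], dtype=float),
            eigenfunction_coeffs=np.asarray(d["eigenfunction_coeffs"], dtype=float),
        )


# ---------------------------------------------------------------------------
# penalized-spline scatterplot smoother (shared by mean and diagonal fits)
# ---------------------------------------------------------------------------

N_CV_FOLDS = 5


def _fold_assignment(n_groups: int, n_folds: int = N_CV_FOLDS) -> np.ndarray:
    return np.arange(n_groups) % max(min(n_folds, n_groups), 1)


def _penalized_fit_1d(
    x: np.ndarray,
    y: np.ndarray,
    basis: SplineBasis,
    penalty: PenaltyMatrix,
    lambdas: np.ndarray = LAMBDA_GRID,
    groups: np.ndarray | None = None,
) -> np.ndarray:
    """P-spline fit of scattered (x, y) with cross-validated smoothing.

    When ``groups`` labels the subject of each observation, smoothing is
    selected by subject-blocked K-fold cross-validation (within-subject
    observations are dependent, so pooled GCV undersmooths); otherwise plain
    GCV is used.
    """
    B = evaluate_basis(basis, x)
    BtB = B.T @ B
    Bty = B.T @ y
    yty = float(y @ y)
    n = y.size
    if groups is not None:
        uniq, gidx = np.unique(groups, return_inverse=True)
        folds = _fold_assignment(len(uniq))[gidx]
        n_folds = folds.max() + 1
        parts = []
        for f in range(n_folds):
            sel = folds == f
            Bf, yf = B[sel], y[sel]
            parts.append((Bf.T @ Bf, Bf.T @ yf, float(yf @ yf)))
    else:
        parts = None
    best = (np.inf, None)
    for lam in lambdas:
        M = BtB + lam * penalty.matrix
        try:
            cf = linalg.cho_factor(M)
        except linalg.LinAlgError as exc:  # pragma: no cover - degenerate data
            raise RankDeficiencyError("singular penalized normal equations") from exc
        if parts is not None:
            score = 0.0
            try:
                for BtB_f, Bty_f, yty_f in parts:
                    coef = linalg.solve(
                        BtB - BtB_f + lam * penalty.matrix, Bty - Bty_f,
                        assume_a="pos",
                    )
                    score += yty_f - 2.0 * coef @ Bty_f + coef @ BtB_f @ coef
            except linalg.LinAlgError:
                score = np.inf
        else:
            coef = linalg.cho_solve(cf, Bty)
            edf = float(np.trace(linalg.cho_solve(cf, BtB)))
            rss = yty - 2.0 * coef @ Bty + coef @ BtB @ coef
            denom = max(n - edf, 1e-10)
            score = n * max(rss, 0.0) / denom**2
        if np.isfinite(score) and score < best[0]:
            best = (score, linalg.cho_solve(cf, Bty))
    if best[1] is None:
        raise RankDeficiencyError("smoothing criterion non-finite on the whole grid")
    return best[1]


def estimate_mean(
    data: list[ObservedFunction],
    basis: SplineBasis,
    penalty: PenaltyMatrix | None = None,
) -> np.ndarray:
    """Penalized-spline estimate of the population mean function.

    All subjects' observations are pooled; smoothing is selected by GCV.
    Returns coefficients of the mean in the supplied basis.
    """
    if penalty is None:
        penalty = difference_penalty(basis.c)
    x = np.concatenate([f.times for f in data])
    y = np.concatenate([f.values for f in data])
    groups = np.concatenate([np.full(f.m, i) for i, f in enumerate(data)])
    if x.size <= basis.c:
        raise RankDeficiencyError(
            f"{x.size} pooled observations cannot identify {basis.c} coefficients"
        )
    return _penalized_fit_1d(x, y, basis, penalty, groups=groups)


# ---------------------------------------------------------------------------
# covariance surface estimation
# ---------------------------------------------------------------------------

def estimate_covariance(
    data: list[ObservedFunction],
    mean_coeffs: np.ndarray,
    basis: SplineBasis,
    penalty: PenaltyMatrix | None = None,
    lambdas: np.ndarray = LAMBDA_GRID,
) -> CovarianceModel:
    """Estimate the smooth covariance surface and nugget variance.

    Demeaned residuals' off-diagonal cross-products ``r_ij r_ik`` (j != k)
    are regressed on the tensor-product basis ``B(t_ij) (x) B(t_ik)`` with a
    symmetric difference penalty selected by subject-blocked
    cross-validation; the coefficient matrix is symmetrized and projected
    onto the PSD cone.  The nugget ``sigma2`` is estimated separately by the
    difference-based route: the intercept of a regression of half squared
    residual differences on squared lag over small within-subject lags
    (``E[(r_ij - r_ik)^2 / 2] = sigma2 + O(lag^2)`` for smooth processes),
    which decouples it from the surface's smoothing bias.
    """
    if penalty is None:
        penalty = difference_penalty(basis.c)
    c = basis.c
    with_pairs = [f for f in data if f.m >= 2]
    if not with_pairs:
        raise IdentifiabilityError(
            "no subject has two or more observations; covariance unidentified"
        )
    residuals = []
    for f in with_pairs:
        B = evaluate_basis(basis, f.times)
        residuals.append((f.times, f.values - B @ mean_coeffs))
    error_var = _nugget_by_differencing(residuals, basis)
    gamma = _wls_surface(residuals, basis, penalty, lambdas, None)
    evals, coeffs = _eigendecompose_gamma(gamma, basis)
    return CovarianceModel(
        basis=basis,
        mean_coeffs=np.asarray(mean_coeffs, dtype=float),
        gamma=gamma,
        error_var=error_var,
        eigenvalues=evals,
        eigenfunction_coeffs=coeffs,
    )


def project_psd(gamma: np.ndarray) -> np.ndarray:
    """Project a symmetric matrix onto the PSD cone by zeroing negative eigenvalues."""
    w, V = linalg.eigh(0.5 * (gamma + gamma.T))
    w = np.maximum(w, 0.0)
    return (V * w) @ V.T


def _wls_surface(
    residuals: list[tuple[np.ndarray, np.ndarray]],
    basis: SplineBasis,
    penalty: PenaltyMatrix,
    lambdas: np.ndarray,
    weights: list[np.ndarray] | None,
) -> np.ndarray:
    """(Weighted) penalized tensor regression of off-diagonal cross-products.

    Separable per-observation weights keep the Kronecker assembly exact:
    the pair (j, k) receives weight w_j w_k.
    """
    c = basis.c
    n_subj = len(residuals)
    n_folds = max(min(N_CV_FOLDS, n_subj), 1)
    folds = _fold_assignment(n_subj, n_folds)
    A_f = np.zeros((n_folds, c * c, c * c))
    rhs_f = np.zeros((n_folds, c * c))
    ssy_f = np.zeros(n_folds)
    n_pairs = 0
    for i, (t, r) in enumerate(residuals):
        B = evaluate_basis(basis, t)
        if weights is not None:
            sw = np.sqrt(weights[i])
            B = B * sw[:, None]
            r = r * sw
        BtB = B.T @ B
        u = B.T @ r
        k = folds[i]
        A_f[k] += np.kron(BtB, BtB)
        A_f[k] -= np.einsum("ja,jb,jc,jd->acbd", B, B, B, B).reshape(c * c, c * c)
        rhs_f[k] += np.kron(u, u) - np.einsum("j,ja,jc->ac", r**2, B, B).ravel()
        s2 = float(np.sum(r**2))
        ssy_f[k] += s2**2 - float(np.sum(r**4))
        n_pairs += t.size * (t.size - 1)
    A = A_f.sum(axis=0)
    rhs = rhs_f.sum(axis=0)
    I_c = np.eye(c)
    P2 = np.kron(penalty.matrix, I_c) + np.kron(I_c, penalty.matrix)
    best = (np.inf, None)
    for lam in lambdas:
        # subject-blocked cross-validation: predict each held-out fold's
        # residual cross-products from the remaining folds' fit
        score = 0.0
        ok = True
        for k in range(n_folds):
            try:
                g = linalg.solve(
                    A - A_f[k] + lam * P2, rhs - rhs_f[k], assume_a="pos"
                )
            except linalg.LinAlgError:
                ok = False
                break
            score += ssy_f[k] - 2.0 * g @ rhs_f[k] + g @ A_f[k] @ g
        if n_folds == 1 and ok:
            # degenerate single-subject case: in-sample GCV
            g = linalg.solve(A + lam * P2, rhs, assume_a="pos")
            edf = float(np.trace(linalg.solve(A + lam * P2, A, assume_a="pos")))
            rss = max(ssy_f[0] - 2.0 * g @ rhs + g @ A @ g, 0.0)
            score = n_pairs * rss / max(n_pairs - edf, 1e-10) ** 2
        if ok and np.isfinite(score) and score < best[0]:
            best = (score, lam)
    if best[1] is None:
        raise RankDeficiencyError("covariance smoothing failed on all lambdas")
    gamma = linalg.solve(A + best[1] * P2, rhs, assume_a="pos").reshape(c, c)
    gamma = 0.5 * (gamma + gamma.T)
    return project_psd(gamma)


#: nugget estimation uses within-subject pairs with lag below this fraction
#: of the domain span
NUGGET_LAG_FRACTION = 0.1


def _nugget_by_differencing(
    residuals: list[tuple[np.ndarray, np.ndarray]],
    basis: SplineBasis,
    lag_fraction: float = NUGGET_LAG_FRACTION,
) -> float:
    """Difference-based nugget: intercept of 0.5 (r_j - r_k)^2 on lag^2."""
    t_min, t_max = basis.boundary
    h0 = lag_fraction * (t_max - t_min)
    hs, ys = [], []
    for t, r in residuals:
        if t.size < 2:
            continue
        iu = np.triu_indices(t.size, 1)
        lag = np.abs(t[:, None] - t[None, :])[iu]
        half_sq = (0.5 * (r[:, None] - r[None, :]) ** 2)[iu]
        sel = lag <= h0
        hs.append(lag[sel])
        ys.append(half_sq[sel])
    h = np.concatenate(hs)
    y = np.concatenate(ys)
    if h.size < 10:  # widen the window for extremely sparse designs
        h = np.concatenate([lag for lag, _ in _all_pairs(residuals)])
        y = np.concatenate([v for _, v in _all_pairs(residuals)])
        keep = h <= np.quantile(h, 0.2)
        h, y = h[keep], y[keep]
    X = np.column_stack([np.ones_like(h), h**2])
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    return float(max(beta[0], 0.0))


def _all_pairs(residuals):
    out = []
    for t, r in residuals:
        if t.size < 2:
            continue
        iu = np.triu_indices(t.size, 1)
        out.append(
            (
                np.abs(t[:, None] - t[None, :])[iu],
                (0.5 * (r[:, None] - r[None, :]) ** 2)[iu],
            )
        )
    return out


# ---------------------------------------------------------------------------
# eigen-decomposition of the covariance operator
# ---------------------------------------------------------------------------

def _eigendecompose_gamma(
    gamma: np.ndarray, basis: SplineBasis, n_grid: int = 2049
) -> tuple[np.ndarray, np.ndarray]:
    G = gram_matrix(basis, n_grid)
    w, U = linalg.eigh(G)
    w = np.maximum(w, 1e-14)
    W = (U * np.sqrt(w)) @ U.T
    W_inv = (U / np.sqrt(w)) @ U.T
    lam, E = linalg.eigh(W @ gamma @ W)
    order = np.argsort(lam)[::-1]
    lam = np.maximum(lam[order], 0.0)
    coeffs = W_inv @ E[:, order]
    total = lam.sum()
    if total > 0:
        share = np.cumsum(lam) / total
        K = int(np.searchsorted(share, EIGEN_SHARE) + 1)
    else:
        K = 1
    K = min(K, basis.c)
    return lam[:K], coeffs[:, :K]


def eigendecompose(
    model: CovarianceModel, n_grid: int = 2049
) -> tuple[np.ndarray, np.ndarray]:
    """Eigenpairs of the integral operator with kernel ``C``.

    Returns nonincreasing eigenvalues and the basis coefficients of
    L2-orthonormal eigenfunctions; their sum matches ``int C(t,t) dt``.
    """
    return _eigendecompose_gamma(model.gamma, model.basis, n_grid)


# ---------------------------------------------------------------------------
# BLUP curve reconstruction
# ---------------------------------------------------------------------------

def blup_curve(
    model: CovarianceModel,
    obs: ObservedFunction | None,
    t_new: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Best linear unbiased prediction of the latent curve at ``t_new``.

    With no observations the prior mean and variance are returned.  The
    pointwise variance is the Gaussian conditional variance
    ``C(t,t) - C(t,t_i)' K^{-1} C(t_i,t)`` with ``K = C(t_i,t_i) + sigma2 I``.
    """
    t_new = np.atleast_1d(np.asarray(t_new, dtype=float))
    prior_var = np.maximum(model.var_at(t_new), 0.0)
    if obs is None or obs.m == 0:
        return model.mean_at(t_new), prior_var
    K = model.cov_between(obs.times, obs.times) + model.error_var * np.eye(obs.m)
    c_ts = model.cov_between(t_new, obs.times)
    resid = obs.values - model.mean_at(obs.times)
    if model.error_var <= 0:
        if np.any(np.diff(obs.times) == 0):
            raise SingularityError(
                "zero error variance with duplicated observation times; "
                "add jitter or a positive nugget"
            )
        # noiseless kernel may be numerically singular; the pseudo-inverse
        # keeps interpolation exact on the range of K
        K_inv = np.linalg.pinv(K, rcond=1e-12, hermitian=True)
        pred = model.mean_at(t_new) + c_ts @ (K_inv @ resid)
        reduction = np.einsum("ij,jk,ik->i", c_ts, K_inv, c_ts)
        return pred, np.maximum(prior_var - reduction, 0.0)
    try:
        cf = linalg.cho_factor(K)
    except linalg.LinAlgError as exc:
        raise SingularityError(
            "singular BLUP kernel matrix; consider adding jitter"
        ) from exc
    pred = model.mean_at(t_new) + c_ts @ linalg.cho_solve(cf, resid)
    reduction = np.einsum("ij,ji->i", c_ts, linalg.cho_solve(cf, c_ts.T))
    var = np.maximum(prior_var - reduction, 0.0)
    return pred, var


# ---------------------------------------------------------------------------
# plain-text interfaces
# ---------------------------------------------------------------------------

def read_functional_csv(path) -> list[ObservedFunction]:
    """Read long-format (id, time, value) CSV into per-subject functions."""
    df = pd.read_csv(path, float_precision="round_trip")
    out = []
    for _, grp in df.groupby("id", sort=True):
        out.append(ObservedFunction(grp["time"].to_numpy(), grp["value"].to_numpy()))
    return out


def covariance_grid(model: CovarianceModel, n: int = 51) -> pd.DataFrame:
    """Gridded covariance surface as a tidy (s, t, C) table for plotting."""
    t_min, t_max = model.basis.boundary
    g = np.linspace(t_min, t_max, n)
    C = model.cov_between(g, g)
    s_idx, t_idx = np.meshgrid(g, g, indexing="ij")
    return pd.DataFrame({"s": s_idx.ravel(), "t": t_idx.ravel(), "C": C.ravel()})
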