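"""Dynamic prediction of future trajectories for out-of-sample subjects.

Given a fitted model and a new subject's partial history ``(t_j, Y_j, Z_j)``,
the subject's random-intercept coefficients are predicted by their BLUP

    u~ = Gamma B*' (B* Gamma B*' + sigma2 I)^{-1} (y - X theta),

and the trajectory by ``Y~(t) = X(t) theta + B(t)' u~`` with pointwise
prediction variance

    B(t)' [Gamma - Gamma B*' (B* Gamma B*' + sigma2 I)^{-1} B* Gamma] B(t)
        + sigma2,

yielding ``Y~(t) +/- 2 sd`` pointwise 95% limits.  Prediction is refused
beyond ``T_max``, the latest outcome time seen in training: extrapolating
past all observed data is not meaningful for this model.  Time-varying
covariates at history and future times are replaced by BLUP reconstructions
conditioned on the subject's own covariate history.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import linalg

from .basis import evaluate_basis
from .containers import ObservedSubject
from .exceptions import ConfigurationError, ExtrapolationError
from .fpca import ObservedFunction, blup_curve
from .model import FCRFit

#: pointwise prediction-interval multiplier (approximate 95%)
PREDICTION_MULTIPLIER = 2.0


@dataclass
class PredictionResult:
    """A predicted trajectory with pointwise 95% limits."""

    t_grid: np.ndarray
    y_hat: np.ndarray
    u_tilde: np.ndarray
    var: np.ndarray
    lo95: np.ndarray
    hi95: np.ndarray
    t_max: float
    conditioning_cutoff: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "t": self.t_grid,
                "y_hat": self.y_hat,
                "sd": np.sqrt(self.var),
                "lo95": self.lo95,
                "hi95": self.hi95,
                "cutoff": self.conditioning_cutoff,
            }
        )


def _check_grid(t_grid: np.ndarray, t_max: float) -> np.ndarray:
    t_grid = np.atleast_1d(np.asarray(t_grid, dtype=float))
    slack = 1e-8 * max(abs(t_max), 1.0)
    if np.any(t_grid > t_max + slack):
        raise ExtrapolationError(
            f"prediction grid exceeds T_max={t_max}; extrapolating beyond all "
            "observed data is not supported"
        )
    return np.minimum(t_grid, t_max)


def _fixed_part(
    fit: FCRFit,
    subject: ObservedSubject,
    times: np.ndarray,
    future_covariates: dict[str, np.ndarray] | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Design rows X(t) at arbitrary times and the fixed-effect prediction.

    Time-varying covariates come from the stored covariate-process BLUP
    conditioned on the subject's covariate history, unless an explicit
    future path is supplied.
    """
    B = evaluate_basis(fit.basis, times)
    cols = [B]
    for name in fit.block_names[1:]:
        if name in fit.tvc_names:
            if future_covariates and name in future_covariates:
                z = np.asarray(future_covariates[name], dtype=float)
            else:
                vals = subject.tvc.get(name)
                obs = None
                if vals is not None:
                    ok = np.isfinite(vals)
                    if ok.any():
                        obs = ObservedFunction(subject.times[ok], vals[ok])
                z, _ = blup_curve(fit.covariate_models[name], obs, times)
        else:
            z = np.full(times.size, float(subject.covariates[name]))
        cols.append(z[:, None] * B)
    X = np.hstack(cols)
    return X, X @ fit.theta


def predict_trajectory(
    fit: FCRFit,
    history: ObservedSubject | None,
    t_grid: np.ndarray,
    future_covariates: dict[str, np.ndarray] | None = None,
) -> PredictionResult:
    """BLUP prediction of a new subject's trajectory on ``t_grid``.

    ``history`` may be empty (population-level prediction).  Parameter
    estimates are plugged in; their sampling uncertainty is not propagated
    into the prediction variance.
    """
    t_grid = _check_grid(t_grid, fit.t_max)
    gamma = fit.gamma
    sigma2 = fit.sigma2_eps
    c = fit.basis.c
    if history is None:
        history = ObservedSubject(subject_id=None, times=[], y=[])
    if history.m > 0:
        X_hist, fixed_hist = _fixed_part(fit, history, history.times)
        B_star = X_hist[:, :c]
        K = B_star @ gamma @ B_star.T + sigma2 * np.eye(history.m)
        K_inv_resid = linalg.solve(K, history.y - fixed_hist, assume_a="pos")
        u_tilde = gamma @ B_star.T @ K_inv_resid
        gamma_post = gamma - gamma @ B_star.T @ linalg.solve(
            K, B_star @ gamma, assume_a="pos"
        )
        cutoff = float(history.times.max())
    else:
        u_tilde = np.zeros(c)
        gamma_post = gamma
        cutoff = -np.inf
    B_grid_X, fixed_grid = _fixed_part(fit, history, t_grid, future_covariates)
    B_grid = B_grid_X[:, :c]
    y_hat = fixed_grid + B_grid @ u_tilde
    var = np.einsum("ij,jk,ik->i", B_grid, gamma_post, B_grid) + sigma2
    var = np.maximum(var, sigma2 if sigma2 > 0 else 0.0)
    sd = np.sqrt(var)
    return PredictionResult(
        t_grid=t_grid,
        y_hat=y_hat,
        u_tilde=u_tilde,
        var=var,
        lo95=y_hat - PREDICTION_MULTIPLIER * sd,
        hi95=y_hat + PREDICTION_MULTIPLIER * sd,
        t_max=fit.t_max,
        conditioning_cutoff=cutoff,
    )


@dataclass
class ScheduleEntry:
    cutoff: float
    window: tuple[float, float]
    result: PredictionResult


def dynamic_prediction_schedule(
    fit,
    subject: ObservedSubject,
    cutoffs: np.ndarray,
    windows: list[tuple[float, float]],
    n_grid: int = 25,
    grid: np.ndarray | None = None,
    pairs: list[tuple[float, tuple[float, float]]] | None = None,
    predictor=None,
) -> list[ScheduleEntry]:
    """One prediction per valid (cutoff, window) pair.

    The cross-product of ``cutoffs`` and ``windows`` is filtered to pairs
    whose window starts after the cutoff and ends by ``T_max``; explicitly
    supplied ``pairs`` are instead validated strictly, raising
    :class:`ConfigurationError` on a window preceding its cutoff.
    """
    if predictor is None:
        predictor = predict_trajectory
    if pairs is None:
        candidate = [(float(co), (float(a), float(b))) for co in cutoffs
                     for (a, b) in windows]
        strict = False
    else:
        candidate = [(float(co), (float(a), float(b))) for co, (a, b) in pairs]
        strict = True
    out = []
    for cutoff, (a, b) in candidate:
        valid = (a > cutoff) and (b > a) and (a <= fit.t_max)
        if not valid:
            if strict:
                raise ConfigurationError(
                    f"window [{a}, {b}] incompatible with cutoff {cutoff}"
                )
            continue
        b_eff = min(b, fit.t_max)
        if grid is not None:
            t_grid = grid[(grid >= a) & (grid <= b_eff)]
        else:
            t_grid = np.linspace(a, b_eff, n_grid)
        history = subject.restrict(cutoff)
        out.append(
            ScheduleEntry(
                cutoff=cutoff,
                window=(a, b),
                result=predictor(fit, history, t_grid),
            )
        )
    return out


def schedule_to_frame(entries: list[ScheduleEntry], subject_id=None) -> pd.DataFrame:
    """Flatten a prediction schedule to a tidy CSV-ready table."""
    frames = []
    for e in entries:
        df = e.result.to_frame()
        df.insert(0, "window_end", e.window[1])
        df.insert(0, "window_start", e.window[0])
        if subject_id is not None:
            df.insert(0, "id", subject_id)
        frames.append(df)
    return pd.concat(frames, ignore_index=True)


def plot_dynamic_prediction(subject: ObservedSubject, entries, ax=None):
    """Observed points plus predicted trajectories with 95% limits."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    ax.scatter(subject.times, subject.y, s=12, color="k", label="observed")
    for e in entries:
        r = e.result
        ax.plot(r.t_grid, r.y_hat, color="crimson")
        ax.plot(r.t_grid, r.lo95, color="crimson", ls="--", lw=0.8)
        ax.plot(r.t_grid, r.hi95, color="crimson", ls="--", lw=0.8)
        ax.axvline(e.cutoff, color="grey", ls=":", lw=0.8)
    ax.set_xlabel("time")
    ax.set_ylabel("outcome")
    return ax
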