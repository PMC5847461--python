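"""B-spline bases with quantile-placed knots and discrete difference penalties.

The mean structure and the functional random intercept are both expanded in a
common cubic B-spline system ``B(t) = {B_1(t), ..., B_c(t)}'`` where ``c``
equals the number of interior knots plus the spline order.  Smoothness is
enforced through a difference penalty ``lambda * D'D`` on adjacent basis
coefficients (a P-spline), with ``D`` the o-th order differencing matrix.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import BSpline

from .exceptions import DegenerateKnotsError, DomainError, InvalidPenaltyError

logger = logging.getLogger(__name__)

#: default number of basis functions for coefficient functions and the
#: functional random intercept (interior knots + order)
DEFAULT_NBASIS = 10
#: default spline order (4 = cubic)
DEFAULT_ORDER = 4
#: default difference-penalty order
DEFAULT_PENALTY_ORDER = 2
#: relative tolerance for clamping near-boundary evaluation points
BOUNDARY_CLAMP_RTOL = 1e-8


@dataclass(frozen=True)
class SplineBasis:
    """A B-spline basis on a bounded time domain.

    Parameters
    ----------
    order
        Spline order (degree + 1); 4 gives cubic splines.
    interior_knots
        Knot locations strictly inside the boundary, nondecreasing.
    boundary
        ``(t_min, t_max)`` of the domain.
    """

    order: int
    interior_knots: np.ndarray
    boundary: tuple[float, float]

    def __post_init__(self) -> None:
        knots = np.asarray(self.interior_knots, dtype=float)
        object.__setattr__(self, "interior_knots", knots)
        t_min, t_max = self.boundary
        if not t_min < t_max:
            raise DomainError(f"empty domain [{t_min}, {t_max}]")
        if knots.size and (knots.min() <= t_min or knots.max() >= t_max):
            raise DegenerateKnotsError(
                "interior knots must lie strictly inside the boundary"
            )
        if np.any(np.diff(knots) < 0):
            raise DegenerateKnotsError("interior knots must be nondecreasing")

    @property
    def c(self) -> int:
        """Number of basis functions: interior knots + order."""
        return self.interior_knots.size + self.order

    @property
    def knot_vector(self) -> np.ndarray:
        """Full knot vector with order-fold replicated boundary knots."""
        t_min, t_max = self.boundary
        return np.concatenate(
            [np.full(self.order, t_min), self.interior_knots, np.full(self.order, t_max)]
        )

    def to_dict(self) -> dict:
        return {
            "order": int(self.order),
            "interior_knots": [float(k) for k in self.interior_knots],
            "boundary": [float(self.boundary[0]), float(self.boundary[1])],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SplineBasis":
        return cls(
            order=int(d["order"]),
            interior_knots=np.asarray(d["interior_knots"], dtype=float),
            boundary=(float(d["boundary"][0]), float(d["boundary"][1])),
        )


@dataclass(frozen=True)
class PenaltyMatrix:
    """Difference penalty ``D'D`` of order ``o`` on ``c`` coefficients."""

    order_of_difference: int
    difference_operator: np.ndarray = field(repr=False)
    matrix: np.ndarray = field(repr=False)

    @property
    def c(self) -> int:
        return self.matrix.shape[0]


def build_basis(
    times: np.ndarray,
    n_interior: int = DEFAULT_NBASIS - DEFAULT_ORDER,
    order: int = DEFAULT_ORDER,
) -> SplineBasis:
    """Build a B-spline basis with interior knots at quantiles of ``times``.

    Interior knots sit at the ``j/(n_interior+1)`` empirical quantiles of the
    pooled observed time points, ``j = 1..n_interior``; the boundary is the
    observed time range.  Duplicated quantiles (heavily tied data) are
    collapsed, reducing ``c``, with a logged warning.
    """
    times = np.asarray(times, dtype=float).ravel()
    if times.size == 0:
        raise DegenerateKnotsError("no time points supplied")
    if n_interior < 0:
        raise ValueError("n_interior must be >= 0")
    if order < 2:
        raise ValueError("order must be >= 2")
    uniq = np.unique(times)
    if uniq.size < n_interior + 2:
        raise DegenerateKnotsError(
            f"{uniq.size} distinct times cannot support {n_interior} interior knots"
        )
    t_min, t_max = float(uniq[0]), float(uniq[-1])
    if n_interior > 0:
        probs = np.arange(1, n_interior + 1) / (n_interior + 1)
        knots = np.quantile(times, probs)
        eps = 1e-10 * (t_max - t_min)
        inside = (knots > t_min + eps) & (knots < t_max - eps)
        kept = np.unique(knots[inside])
        if kept.size < n_interior:
            msg = (
                f"collapsed {n_interior - kept.size} duplicate/boundary interior "
                f"knots; basis dimension reduced to {kept.size + order}"
            )
            logger.warning(msg)
            warnings.warn(msg, stacklevel=2)
        knots = kept
    else:
        knots = np.empty(0)
    return SplineBasis(order=order, interior_knots=knots, boundary=(t_min, t_max))


def evaluate_basis(basis: SplineBasis, t: np.ndarray) -> np.ndarray:
    """Evaluate all basis functions at ``t``; rows sum to one.

    Points outside the domain by less than ``1e-8`` of its range are clamped
    (floating-point guard); larger excursions raise :class:`DomainError`.
    """
    t = np.atleast_1d(np.asarray(t, dtype=float))
    t_min, t_max = basis.boundary
    slack = BOUNDARY_CLAMP_RTOL * (t_max - t_min)
    if np.any(t < t_min - slack) or np.any(t > t_max + slack):
        bad = t[(t < t_min - slack) | (t > t_max + slack)]
        raise DomainError(
            f"evaluation points outside domain [{t_min}, {t_max}]: {bad[:5]}"
        )
    t = np.clip(t, t_min, t_max)
    mat = BSpline.design_matrix(t, basis.knot_vector, basis.order - 1).toarray()
    return mat


def difference_penalty(c: int, o: int = DEFAULT_PENALTY_ORDER) -> PenaltyMatrix:
    """Construct the o-th order difference penalty ``D'D`` for ``c`` coefficients.

    ``D`` is the ``(c-o) x c`` differencing matrix; the penalty null space
    spans polynomials of degree ``< o`` in the coefficient index.
    """
    if not 0 < o < c:
        raise InvalidPenaltyError(f"difference order o={o} invalid for c={c}")
    D = np.diff(np.eye(c), n=o, axis=0)
    return PenaltyMatrix(order_of_difference=o, difference_operator=D, matrix=D.T @ D)


def gram_matrix(basis: SplineBasis, n_quad: int = 2049) -> np.ndarray:
    """L2 Gram matrix ``G_kl = int B_k(t) B_l(t) dt`` by composite Simpson."""
    t_min, t_max = basis.boundary
    # Simpson needs an odd number of points
    if n_quad % 2 == 0:
        n_quad += 1
    grid = np.linspace(t_min, t_max, n_quad)
    B = evaluate_basis(basis, grid)
    w = _simpson_weights(n_quad, (t_max - t_min) / (n_quad - 1))
    return (B * w[:, None]).T @ B


def _simpson_weights(n: int, h: float) -> np.ndarray:
    w = np.ones(n)
    w[1:-1:2] = 4.0
    w[2:-1:2] = 2.0
    return w * h / 3.0
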