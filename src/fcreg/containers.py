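"""Shared data containers for long-format longitudinal data."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class ObservedSubject:
    """One subject's irregular visits: times, outcomes, covariates.

    ``covariates`` holds time-invariant scalars (e.g. sex indicator);
    ``tvc`` holds error-contaminated time-varying covariate observations
    aligned with ``times`` (NaN marks a missing visit value).
    """

    subject_id: object
    times: np.ndarray
    y: np.ndarray
    covariates: dict[str, float] = field(default_factory=dict)
    tvc: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float).ravel()
        y = np.asarray(self.y, dtype=float).ravel()
        if t.size != y.size:
            raise ValueError("times and y must have equal length")
        order = np.argsort(t, kind="stable")
        self.times = t[order]
        self.y = y[order]
        self.tvc = {
            k: np.asarray(v, dtype=float).ravel()[order] for k, v in self.tvc.items()
        }

    @property
    def m(self) -> int:
        return self.times.size

    def restrict(self, cutoff: float) -> "ObservedSubject":
        """Return a copy containing only visits at or before ``cutoff``."""
        keep = self.times <= cutoff
        return ObservedSubject(
            subject_id=self.subject_id,
            times=self.times[keep],
            y=self.y[keep],
            covariates=dict(self.covariates),
            tvc={k: v[keep] for k, v in self.tvc.items()},
        )
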