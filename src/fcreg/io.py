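"""Long-format data ingestion and fit serialization."""

from __future__ import annotations

import json
import warnings

import numpy as np
import pandas as pd

from .competitors import AMMFit
from .containers import ObservedSubject
from .exceptions import MissingDataError
from .model import FCRFit


def read_long(
    path,
    id_col: str = "id",
    time_col: str = "time",
    outcome_col: str = "y",
    covariates: list[str] = (),
    tvc: list[str] = (),
) -> list[ObservedSubject]:
    """Read one-row-per-visit CSV into per-subject containers.

    Rows are grouped by subject and sorted by time; duplicated (id, time)
    rows are averaged with a warning.  Time-invariant covariates must be
    constant within subject.
    """
    df = pd.read_csv(path, float_precision="round_trip")
    needed = [id_col, time_col, outcome_col, *covariates, *tvc]
    missing = [c for c in needed if c not in df.columns]
    if missing:
        raise MissingDataError(f"columns not found in {path}: {missing}")
    times = pd.to_numeric(df[time_col], errors="coerce")
    if times.isna().any() or not np.isfinite(times).all():
        raise ValueError(f"non-numeric or non-finite values in column '{time_col}'")
    df = df.assign(**{time_col: times})

    if df.duplicated([id_col, time_col]).any():
        warnings.warn(
            "duplicated (id, time) rows found; averaging their values",
            stacklevel=2,
        )
        agg = {outcome_col: "mean", **{c: "mean" for c in [*covariates, *tvc]}}
        df = df.groupby([id_col, time_col], as_index=False, sort=True).agg(agg)

    subjects = []
    for sid, grp in df.groupby(id_col, sort=True):
        grp = grp.sort_values(time_col, kind="stable")
        cov = {}
        for c in covariates:
            vals = grp[c].unique()
            if len(vals) > 1:
                raise MissingDataError(
                    f"covariate '{c}' varies within subject {sid}; "
                    "declare it as time-varying instead"
                )
            cov[c] = float(vals[0])
        subjects.append(
            ObservedSubject(
                subject_id=sid,
                times=grp[time_col].to_numpy(dtype=float),
                y=grp[outcome_col].to_numpy(dtype=float),
                covariates=cov,
                tvc={c: grp[c].to_numpy(dtype=float) for c in tvc},
            )
        )
    return subjects


def write_long(subjects: list[ObservedSubject], path) -> None:
    """Write subjects back to one-row-per-visit CSV (full float precision)."""
    rows = []
    for s in subjects:
        for j in range(s.m):
            row = {"id": s.subject_id, "time": s.times[j], "y": s.y[j]}
            row.update(s.covariates)
            row.update({k: v[j] for k, v in s.tvc.items()})
            rows.append(row)
    # %.17g round-trips IEEE doubles exactly
    pd.DataFrame(rows).to_csv(path, index=False, float_format="%.17g")


def load_fit(path):
    """Load a serialized fit, dispatching on its recorded model type."""
    with open(path) as fh:
        d = json.load(fh)
    kind = d.get("type", "fcr")
    if kind == "amm":
        return AMMFit.from_dict(d)
    return FCRFit.from_dict(d)
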