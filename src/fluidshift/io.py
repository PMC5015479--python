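"""File I/O: CSV contracts for schedules, traces and hemodilution series.

Column contracts (all times in minutes):

* schedule CSV — ``time_min, u_ml_per_min, v_ml_per_min``; each row's rates
  hold until the next row's time, and the final row closes the schedule (its
  time is the study duration; its rates are ignored and conventionally zero).
* trace CSV — ``time_min, vb_frac``.
* hemodilution CSV — ``time_min, hgb, hct`` with hemoglobin in g/l by default
  (g/dl accepted via the unit flag; the conversion itself is unit-invariant)
  and hematocrit as a fraction in (0, 1).

Volumes are ml everywhere in files; the CLI layer converts liters on request.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import InputError
from .hemodilution import HemodilutionSeries
from .model import InputSchedule, ModelParams, VolumeTrace

__all__ = ["read_schedule", "write_schedule", "read_trace", "write_trace",
           "read_hemodilution", "read_params", "write_params"]


def _read_csv(path, required_columns):
    path = Path(path)
    if not path.exists():
        raise InputError(f"no such file: {path}")
    df = pd.read_csv(path)
    missing = [c for c in required_columns if c not in df.columns]
    if missing:
        raise InputError(f"{path}: missing required column(s) {missing}; "
                         f"found {list(df.columns)}")
    if df[list(required_columns)].isna().any().any():
        raise InputError(f"{path}: missing values in required columns")
    return df


def _check_monotone_times(df, path):
    t = df["time_min"].to_numpy(dtype=float)
    bad = np.nonzero(np.diff(t) <= 0)[0]
    if bad.size:
        # offending data row is bad[0]+1 (0-based); +1 header, +1 one-based
        row = int(bad[0]) + 3
        raise InputError(f"{path}: time_min not strictly increasing at row "
                         f"{row} (t = {t[bad[0] + 1]})")
    return t


def read_schedule(path) -> InputSchedule:
    """Read a piecewise-constant input schedule from CSV."""
    df = _read_csv(path, ("time_min", "u_ml_per_min", "v_ml_per_min"))
    if len(df) < 2:
        raise InputError(f"{path}: a schedule needs at least two rows "
                         "(the last row closes the schedule)")
    t = _check_monotone_times(df, path)
    u = df["u_ml_per_min"].to_numpy(dtype=float)
    v = df["v_ml_per_min"].to_numpy(dtype=float)
    for name, col in (("u_ml_per_min", u), ("v_ml_per_min", v)):
        bad = np.nonzero(col[:-1] < 0)[0]
        if bad.size:
            raise InputError(f"{path}: negative {name} at row {int(bad[0]) + 2}")
    return InputSchedule(breakpoints=t[:-1], u_rates=u[:-1], v_rates=v[:-1],
                         duration=float(t[-1]))


def write_schedule(schedule: InputSchedule, path) -> None:
    rows = {
        "time_min": np.append(schedule.breakpoints, schedule.duration),
        "u_ml_per_min": np.append(schedule.u_rates, 0.0),
        "v_ml_per_min": np.append(schedule.v_rates, 0.0),
    }
    pd.DataFrame(rows).to_csv(path, index=False)


def read_trace(path) -> VolumeTrace:
    """Read a fractional blood-volume trace from CSV."""
    df = _read_csv(path, ("time_min", "vb_frac"))
    t = _check_monotone_times(df, path)
    steps = np.diff(t)
    ts = float(steps[0]) if steps.size and np.allclose(steps, steps[0]) else None
    return VolumeTrace(t, df["vb_frac"].to_numpy(dtype=float),
                       sampling_interval=ts)


def write_trace(trace: VolumeTrace, path) -> None:
    pd.DataFrame({"time_min": trace.times,
                  "vb_frac": trace.vb_frac}).to_csv(path, index=False)


def read_hemodilution(path, hgb_units: str = "g/l") -> HemodilutionSeries:
    """Read a paired hemoglobin/hematocrit series from CSV.

    ``hgb_units`` ("g/l" or "g/dl") rescales hemoglobin to g/l internally;
    the dilution formula only uses concentration ratios, so this affects
    stored values and validation messages, not the computed trace.
    """
    if hgb_units not in ("g/l", "g/dl"):
        raise InputError(f"hgb_units must be 'g/l' or 'g/dl', got {hgb_units!r}")
    df = _read_csv(path, ("time_min", "hgb", "hct"))
    t = _check_monotone_times(df, path)
    hgb = df["hgb"].to_numpy(dtype=float)
    if hgb_units == "g/dl":
        hgb = hgb * 10.0
    return HemodilutionSeries(t, hgb, df["hct"].to_numpy(dtype=float))


def read_params(path, volume_units: str = "ml") -> ModelParams:
    """Read a parameter triple from JSON.

    Expected keys: ``alpha``, ``K_per_min`` and ``V_B0_ml`` (or ``V_B0_l``
    when ``volume_units='l'``).
    """
    with open(path) as fh:
        data = json.load(fh)
    key = "V_B0_ml" if volume_units == "ml" else "V_B0_l"
    try:
        vb0 = float(data[key])
        params = ModelParams(alpha=float(data["alpha"]),
                             K=float(data["K_per_min"]),
                             V_B0=vb0 * (1000.0 if volume_units == "l" else 1.0))
    except KeyError as exc:
        raise InputError(f"{path}: missing parameter key {exc}") from None
    return params


def write_params(params: ModelParams, path) -> None:
    with open(path, "w") as fh:
        json.dump({"alpha": params.alpha, "K_per_min": params.K,
                   "V_B0_ml": params.V_B0}, fh, indent=2)
        fh.write("\n")
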