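"""Convert hemoglobin/hematocrit hemodilution series into blood-volume traces.

Hemoglobin is used as an endogenous tracer: assuming its total intravascular
mass is constant, a rise in blood volume dilutes its concentration, so the
fractional blood-volume change can be recovered from paired hemoglobin and
hematocrit measurements:

    V̆_B(t) = [1 / (1 - Hct(t))] * [Hgb(0) - Hgb(t)] / Hgb(t)

The formula is a ratio of concentrations, so it is invariant to the
hemoglobin unit (g/l vs g/dl) as long as the series is internally consistent;
the unit flag exists only for validation messages at the I/O layer.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import InputError, ParameterDomainError
from .model import VolumeTrace

__all__ = ["HemodilutionSeries", "fractional_blood_volume_from_hemodilution",
           "hemoglobin_from_fractional_blood_volume"]


@dataclass(frozen=True)
class HemodilutionSeries:
    """Paired hemoglobin concentration (g/l) and hematocrit (fraction) series.

    A baseline sample at t = 0 is mandatory: the conversion is anchored to
    Hgb(0).
    """

    times: np.ndarray
    hgb: np.ndarray
    hct: np.ndarray

    def __post_init__(self):
        t = np.asarray(self.times, dtype=float)
        hgb = np.asarray(self.hgb, dtype=float)
        hct = np.asarray(self.hct, dtype=float)
        if t.ndim != 1 or t.shape != hgb.shape or t.shape != hct.shape:
            raise InputError("times, hgb and hct must be equal-length 1-D arrays")
        if np.any(np.diff(t) <= 0):
            raise InputError("times must be strictly increasing")
        if t[0] != 0.0:
            raise InputError("a baseline sample at t = 0 is required")
        if np.any(hgb <= 0):
            raise ParameterDomainError("hemoglobin concentrations must be > 0")
        if np.any((hct <= 0) | (hct >= 1)):
            raise ParameterDomainError("hematocrit must lie strictly in (0, 1)")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "hgb", hgb)
        object.__setattr__(self, "hct", hct)


def fractional_blood_volume_from_hemodilution(
        series: HemodilutionSeries, hct_mode: str = "measured") -> VolumeTrace:
    """Fractional blood-volume trace from a hemodilution series.

    Parameters
    ----------
    series : HemodilutionSeries
        Paired Hgb/Hct samples with a baseline at t = 0.
    hct_mode : {"measured", "baseline"}
        "measured" uses the time-varying hematocrit Hct(t) in the plasma
        correction factor 1/(1 - Hct); "baseline" uses the classical
        convention of holding it at Hct(0).

    Returns
    -------
    VolumeTrace
        V̆_B(t), anchored at V̆_B(0) = 0 by construction.
    """
    if hct_mode not in ("measured", "baseline"):
        raise InputError(f"unknown hct_mode {hct_mode!r}")
    hct = series.hct if hct_mode == "measured" else np.full_like(
        series.hct, series.hct[0])
    hgb0 = series.hgb[0]
    vb = (1.0 / (1.0 - hct)) * (hgb0 - series.hgb) / series.hgb
    step = np.diff(series.times)
    ts = float(step[0]) if step.size and np.allclose(step, step[0]) else None
    return VolumeTrace(series.times, vb, sampling_interval=ts)


def hemoglobin_from_fractional_blood_volume(
        trace: VolumeTrace, hgb0: float, hct) -> HemodilutionSeries:
    """Invert the hemodilution formula: synthesize Hgb(t) from a V̆_B trace.

    With the hematocrit fixed (scalar) or given per sample, the unique
    hemoglobin series consistent with the trace is
    ``Hgb(t) = Hgb(0) / (1 + (1 - Hct(t)) V̆_B(t))``.  Useful for round-trip
    validation and for generating synthetic laboratory series.
    """
    if hgb0 <= 0:
        raise ParameterDomainError("baseline hemoglobin must be > 0")
    hct_arr = np.broadcast_to(np.asarray(hct, dtype=float),
                              trace.times.shape).copy()
    if np.any((hct_arr <= 0) | (hct_arr >= 1)):
        raise ParameterDomainError("hematocrit must lie strictly in (0, 1)")
    hgb = hgb0 / (1.0 + (1.0 - hct_arr) * trace.vb_frac)
    return HemodilutionSeries(trace.times, hgb, hct_arr)
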