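"""Two-compartment feedback model of blood-volume response to fluid infusion.

The intravascular/interstitial fluid shift is represented as the output of a
hypothetical proportional feedback controller that drives the blood-volume
change toward a target equal to the fraction 1/(1+alpha) of the accumulated
net fluid input, so that at steady state the intravascular and interstitial
volume changes settle at the ratio 1:alpha.  Three subject-specific constants
characterize the model completely:

* ``alpha`` — target volume ratio (interstitial : intravascular), dimensionless;
* ``K``     — feedback gain, i.e. the speed of inter-compartment fluid shift,
  in 1/min;
* ``V_B0``  — initial (baseline) blood volume in ml, used to normalize the
  output into a fractional blood-volume change.

With net input ``w(t) = u(t) - v(t)`` (infusion minus loss, ml/min) the states
obey the linear system

    d(ΔV_B)/dt = w + K (r_B - ΔV_B),        d(r_B)/dt = w / (1 + alpha),

with ΔV_B(0) = r_B(0) = 0.  The inter-compartment flow is
``q = -K e_B`` where ``e_B = r_B - ΔV_B``; positive ``q`` is a shift from the
intravascular into the interstitial compartment.

All internal units are ml and min.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import cumulative_trapezoid

from .errors import InputError, ParameterDomainError, ScheduleRangeError

__all__ = [
    "ModelParams",
    "InputSchedule",
    "VolumeTrace",
    "SimulationResult",
    "target_blood_volume_change",
    "simulate_response",
    "simulate_difference_equation",
    "reconstruct_interstitial_change",
]


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ModelParams:
    """Subject-specific parameter triple (alpha, K, V_B0).

    Parameters
    ----------
    alpha : float
        Target volume ratio, dimensionless. Must be positive; values below 1
        are legal and typical for colloids, which are retained intravascularly.
    K : float
        Feedback gain in 1/min; sets how fast fluid shifts between the
        compartments per unit volume discrepancy.
    V_B0 : float
        Initial blood volume in ml.
    """

    alpha: float
    K: float
    V_B0: float

    def __post_init__(self):
        if not (self.alpha > 0):
            raise ParameterDomainError(f"alpha must be > 0, got {self.alpha}")
        if not (self.K > 0):
            raise ParameterDomainError(f"K must be > 0, got {self.K}")
        if not (self.V_B0 > 0):
            raise ParameterDomainError(f"V_B0 must be > 0, got {self.V_B0}")

    def as_array(self) -> np.ndarray:
        return np.array([self.alpha, self.K, self.V_B0], dtype=float)


@dataclass(frozen=True)
class InputSchedule:
    """Piecewise-constant infusion rate u(t) and loss rate v(t), ml/min.

    ``breakpoints[k]`` opens segment ``k``; segment ``k`` carries the constant
    rates ``u_rates[k]`` and ``v_rates[k]`` until the next breakpoint (or
    until ``duration`` for the last segment).
    """

    breakpoints: np.ndarray
    u_rates: np.ndarray
    v_rates: np.ndarray
    duration: float

    def __post_init__(self):
        bp = np.asarray(self.breakpoints, dtype=float)
        u = np.asarray(self.u_rates, dtype=float)
        v = np.asarray(self.v_rates, dtype=float)
        if bp.ndim != 1 or bp.size == 0:
            raise InputError("breakpoints must be a non-empty 1-D sequence")
        if bp[0] != 0.0:
            raise InputError("schedule must start at t = 0")
        if np.any(np.diff(bp) <= 0):
            raise InputError("breakpoints must be strictly increasing")
        if u.shape != bp.shape or v.shape != bp.shape:
            raise InputError("one u and one v rate required per segment")
        if np.any(u < 0) or np.any(v < 0):
            raise InputError("infusion and loss rates must be non-negative")
        if self.duration < bp[-1]:
            raise InputError("duration must cover the last breakpoint")
        object.__setattr__(self, "breakpoints", bp)
        object.__setattr__(self, "u_rates", u)
        object.__setattr__(self, "v_rates", v)
        object.__setattr__(self, "duration", float(self.duration))

    # -- rate lookups -------------------------------------------------------
    def _segment_index(self, t: np.ndarray) -> np.ndarray:
        idx = np.searchsorted(self.breakpoints, t, side="right") - 1
        return np.clip(idx, 0, self.breakpoints.size - 1)

    def u(self, t):
        """Infusion rate at time(s) ``t`` (zero before t = 0)."""
        t = np.asarray(t, dtype=float)
        out = self.u_rates[self._segment_index(t)]
        return np.where(t < 0, 0.0, out)

    def v(self, t):
        """Loss rate at time(s) ``t`` (zero before t = 0)."""
        t = np.asarray(t, dtype=float)
        out = self.v_rates[self._segment_index(t)]
        return np.where(t < 0, 0.0, out)

    def net_rate(self, t):
        return self.u(t) - self.v(t)

    def cumulative_net(self, t):
        """Exact integral of u - v from 0 to ``t`` (piecewise-linear in t)."""
        t = np.atleast_1d(np.asarray(t, dtype=float))
        edges = np.append(self.breakpoints, self.duration)
        w = self.u_rates - self.v_rates
        cum_edges = np.concatenate([[0.0], np.cumsum(w * np.diff(edges))])
        idx = self._segment_index(t)
        out = cum_edges[idx] + w[idx] * (t - self.breakpoints[idx])
        return out if out.size > 1 else float(out[0])

    def total_infused(self) -> float:
        edges = np.append(self.breakpoints, self.duration)
        return float(np.sum(self.u_rates * np.diff(edges)))

    def total_lost(self) -> float:
        edges = np.append(self.breakpoints, self.duration)
        return float(np.sum(self.v_rates * np.diff(edges)))

    @staticmethod
    def constant(u: float, v: float, duration: float) -> "InputSchedule":
        """Single-segment schedule with constant rates over [0, duration]."""
        return InputSchedule(np.array([0.0]), np.array([float(u)]),
                             np.array([float(v)]), duration)


@dataclass(frozen=True)
class VolumeTrace:
    """Sampled fractional blood-volume response ΔV_B / V_B0.

    ``sampling_interval`` (T_S, min) is set for uniform grids and is required
    by the difference-equation and regression paths.
    """

    times: np.ndarray
    vb_frac: np.ndarray
    sampling_interval: float | None = None

    def __post_init__(self):
        t = np.asarray(self.times, dtype=float)
        vb = np.asarray(self.vb_frac, dtype=float)
        if t.ndim != 1 or t.shape != vb.shape:
            raise InputError("times and vb_frac must be equal-length 1-D arrays")
        if np.any(np.diff(t) <= 0):
            raise InputError("trace times must be strictly increasing")
        if np.any(vb <= -1.0):
            raise InputError("vb_frac <= -1 implies negative blood volume")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "vb_frac", vb)

    def __len__(self) -> int:
        return self.times.size

    def uniform_step(self) -> float:
        """Return the common sampling step, raising if the grid is non-uniform."""
        steps = np.diff(self.times)
        if not np.allclose(steps, steps[0], rtol=1e-9, atol=1e-12):
            raise InputError("trace is not uniformly sampled")
        return float(steps[0])


@dataclass(frozen=True)
class SimulationResult:
    """Trajectories produced by :func:`simulate_response` (ml, min).

    ``dVISF`` is reconstructed by numerical integration of the flow ``q``, so
    volume conservation ``dVB + dVISF = ∫(u − v)`` holds to quadrature
    tolerance rather than exactly.
    """

    times: np.ndarray
    dVB: np.ndarray
    vb_frac: np.ndarray
    rB: np.ndarray
    eB: np.ndarray
    q: np.ndarray
    dVISF: np.ndarray
    params: ModelParams = field(repr=False, default=None)
    schedule: InputSchedule = field(repr=False, default=None)

    def as_trace(self, sampling_interval: float | None = None) -> VolumeTrace:
        return VolumeTrace(self.times, self.vb_frac, sampling_interval)


# ---------------------------------------------------------------------------
# Continuous-time simulation (segment-exact)
# ---------------------------------------------------------------------------

def target_blood_volume_change(schedule: InputSchedule, alpha: float, t) -> float:
    """Target blood-volume change r_B(t) = 1/(1+alpha) * ∫₀ᵗ (u - v) dτ, ml.

    The integral is evaluated in closed form for the piecewise-constant
    schedule, so the result is exact.
    """
    if not (alpha > 0):
        raise ParameterDomainError(f"alpha must be > 0, got {alpha}")
    t_arr = np.atleast_1d(np.asarray(t, dtype=float))
    if np.any(t_arr < 0) or np.any(t_arr > schedule.duration):
        raise ScheduleRangeError(
            f"t must lie within [0, {schedule.duration}] min")
    out = schedule.cumulative_net(t_arr) / (1.0 + alpha)
    out = np.atleast_1d(out)
    return out if np.ndim(t) else float(out[0])


def _propagate(params: ModelParams, schedule: InputSchedule):
    """Exact state (r_B, e = ΔV_B − r_B) at every segment edge."""
    K, a = params.K, params.alpha
    w = schedule.u_rates - schedule.v_rates
    edges = np.append(schedule.breakpoints, schedule.duration)
    rB = np.zeros(edges.size)
    e = np.zeros(edges.size)
    gain = a / (K * (1.0 + a))
    for k in range(edges.size - 1):
        dt = edges[k + 1] - edges[k]
        decay = np.exp(-K * dt)
        rB[k + 1] = rB[k] + w[k] * dt / (1.0 + a)
        e[k + 1] = e[k] * decay + w[k] * gain * (1.0 - decay)
    return edges, rB, e, w


def simulate_response(params: ModelParams, schedule: InputSchedule,
                      time_grid) -> SimulationResult:
    """Simulate the blood-volume response on ``time_grid`` (min).

    The model is linear time-invariant and the inputs are piecewise constant,
    so each segment admits a closed-form solution: the discrepancy
    ``e = ΔV_B − r_B`` relaxes exponentially at rate K toward
    ``w·alpha/(K(1+alpha))`` while r_B grows linearly.  The trajectory is
    therefore exact to round-off; no ODE stepper is involved.
    """
    t = np.asarray(time_grid, dtype=float)
    if t.ndim != 1 or t.size == 0:
        raise InputError("time_grid must be a non-empty 1-D sequence")
    if t[0] != 0.0:
        raise InputError("time_grid must start at t = 0")
    if np.any(np.diff(t) <= 0):
        raise InputError("time_grid must be strictly increasing")
    if t[-1] > schedule.duration * (1 + 1e-12):
        raise ScheduleRangeError("time_grid extends past the schedule duration")

    K, a = params.K, params.alpha
    edges, rB_e, e_e, w = _propagate(params, schedule)
    idx = np.clip(np.searchsorted(edges, t, side="right") - 1, 0, w.size - 1)
    dt = t - edges[idx]
    decay = np.exp(-K * dt)
    gain = a / (K * (1.0 + a))
    rB = rB_e[idx] + w[idx] * dt / (1.0 + a)
    e = e_e[idx] * decay + w[idx] * gain * (1.0 - decay)

    dVB = rB + e
    q = K * e                      # q = -K e_B with e_B = r_B - ΔV_B = -e
    eB = -e
    dVISF = _integrate_flow(t, q)
    return SimulationResult(times=t, dVB=dVB, vb_frac=dVB / params.V_B0,
                            rB=rB, eB=eB, q=q, dVISF=dVISF,
                            params=params, schedule=schedule)


def _integrate_flow(times: np.ndarray, q: np.ndarray) -> np.ndarray:
    if times.size == 1:
        return np.zeros(1)
    return cumulative_trapezoid(q, times, initial=0.0)


def reconstruct_interstitial_change(sim: SimulationResult) -> np.ndarray:
    """Interstitial volume change, ml, as the numerical integral of q.

    Cumulative trapezoidal quadrature of the inter-compartment flow on the
    simulation grid; together with ΔV_B it conserves the net fluid input to
    quadrature tolerance.
    """
    q = np.asarray(sim.q, dtype=float)
    t = np.asarray(sim.times, dtype=float)
    if q.shape != t.shape:
        raise InputError("simulation q and times are inconsistent")
    return _integrate_flow(t, q)


# ---------------------------------------------------------------------------
# Euler difference equation
# ---------------------------------------------------------------------------

def simulate_difference_equation(params: ModelParams, schedule: InputSchedule,
                                 T_S: float, N: int) -> VolumeTrace:
    """Fractional blood volume via the first-order Euler difference equation.

    Discretizes the second-order input/output form with backward differences
    on both the output and the inputs and the forcing evaluated two samples
    back:

        V(i) = 2 V(i-1) - V(i-2) - K T_S [V(i-1) - V(i-2)]
             + (T_S / V_B0) {[u(i-1) - u(i-2)] - [v(i-1) - v(i-2)]}
             + (K T_S² / (V_B0 (1+alpha))) [u(i-2) - v(i-2)]

    with startup convention V(0) = V(-1) = 0 and u = v = 0 before t = 0.
    The recursion is first-order accurate in T_S and marginally stable for
    K·T_S < 2; a warning is emitted when that margin is violated.
    """
    if not (T_S > 0):
        raise InputError("T_S must be positive")
    if N < 3:
        raise InputError("need at least N = 3 steps")
    if N * T_S > schedule.duration * (1 + 1e-12):
        raise ScheduleRangeError("N*T_S extends past the schedule duration")
    K, a, V0 = params.K, params.alpha, params.V_B0
    if K * T_S >= 2.0:
        warnings.warn(
            f"K*T_S = {K * T_S:.3g} >= 2: Euler recursion is unstable; "
            "reduce the sampling interval", stacklevel=2)

    times = np.arange(N + 1) * T_S
    # sample inputs on the same clock, with one pre-baseline sample at -T_S
    sample_t = np.concatenate([[-T_S], times])
    u = np.asarray(schedule.u(sample_t), dtype=float)
    v = np.asarray(schedule.v(sample_t), dtype=float)
    w = u - v                       # w[j] is the net rate at time (j-1)*T_S

    vb = np.zeros(N + 2)            # vb[j] is V at time (j-1)*T_S; vb[0]=V(-1)
    c_in = T_S / V0
    c_force = K * T_S * T_S / (V0 * (1.0 + a))
    for i in range(1, N + 1):
        j = i + 1                   # index into the padded arrays
        vb[j] = (2.0 * vb[j - 1] - vb[j - 2]
                 - K * T_S * (vb[j - 1] - vb[j - 2])
                 + c_in * (w[j - 1] - w[j - 2])
                 + c_force * w[j - 2])
    return VolumeTrace(times, vb[1:], sampling_interval=T_S)
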