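"""Reference infusion protocols, fitted-parameter fixtures and synthetic data.

Seven bolus-infusion protocols from three published hemodilution studies are
encoded here together with the parameter values obtained by fitting the model
to the protocol-average responses of those studies:

* three Ringer's acetate protocols (25 ml/kg over 30 min, 150 min
  post-infusion observation) under 0, 450 and 900 ml of pre-infusion
  hemorrhage;
* two crystalloid protocols (0.9% saline, Ringer's lactate; 25 ml/kg over
  30 min, 210 min observation);
* two colloid protocols (5% albumin, autologous plasma; 10 ml/kg over
  30 min, 450 min observation).

The source fractional-blood-volume curves themselves are not distributable
(they were digitized from figures), so this module also generates synthetic
traces by forward-simulating the protocols under the reference parameters
with additive Gaussian measurement noise — the package's test bed for
parameter-recovery experiments.

Pre-infusion hemorrhage is deliberately NOT placed in the loss rate v(t): it
precedes the study clock, and its effect is carried entirely by the smaller
baseline blood volume of the corresponding parameter set.  The source studies
report no per-protocol urine totals, so fixtures default to v = 0 with an
explicit ``total_urine_ml`` hook.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .errors import InputError
from .estimation import FitOptions, fit_model
from .model import InputSchedule, ModelParams, VolumeTrace, simulate_response

__all__ = ["ProtocolSpec", "ReferenceFit", "PROTOCOLS", "REFERENCE_FITS",
           "schedule_from_protocol", "generate_synthetic_trace",
           "parameter_recovery_experiment", "reference_params"]

#: Default subject weight, kg, used when a protocol does not set one (the
#: source studies report only ranges such as 65-85 kg).
DEFAULT_WEIGHT_KG = 75.0


@dataclass(frozen=True)
class ProtocolSpec:
    """A bolus-infusion study protocol.

    ``dose_ml_per_kg`` is infused at a constant rate over
    ``infusion_time_min``; the subject is then observed for
    ``observation_time_min`` with no further input.  ``hemorrhage_ml`` is
    pre-infusion blood loss (metadata only; see module docstring).
    """

    name: str
    fluid_class: str                 # "crystalloid" | "colloid"
    dose_ml_per_kg: float
    infusion_time_min: float
    observation_time_min: float
    hemorrhage_ml: float = 0.0
    weight_kg: float | None = None
    total_urine_ml: float | None = None

    def __post_init__(self):
        if self.dose_ml_per_kg <= 0:
            raise InputError("dose must be positive")
        if self.infusion_time_min <= 0 or self.observation_time_min <= 0:
            raise InputError("protocol times must be positive")
        if self.hemorrhage_ml < 0:
            raise InputError("hemorrhage volume cannot be negative")

    @property
    def duration_min(self) -> float:
        return self.infusion_time_min + self.observation_time_min


@dataclass(frozen=True)
class ReferenceFit:
    """Fitted parameters and error metrics for one reference protocol.

    ``V_B0_l`` is in liters as conventionally reported; error metrics are in
    percent of the average measured fractional blood volume.
    """

    K: float
    V_B0_l: float
    alpha: float
    error_mean_pct: float
    error_sd_pct: float
    rmse_pct: float

    def params(self) -> ModelParams:
        return ModelParams(alpha=self.alpha, K=self.K,
                           V_B0=self.V_B0_l * 1000.0)


def _crystalloid(name, hemorrhage=0.0, observation=150.0):
    return ProtocolSpec(name=name, fluid_class="crystalloid",
                        dose_ml_per_kg=25.0, infusion_time_min=30.0,
                        observation_time_min=observation,
                        hemorrhage_ml=hemorrhage)


def _colloid(name):
    return ProtocolSpec(name=name, fluid_class="colloid",
                        dose_ml_per_kg=10.0, infusion_time_min=30.0,
                        observation_time_min=450.0)


PROTOCOLS: dict[str, ProtocolSpec] = {
    "ringers_acetate_0ml": _crystalloid("ringers_acetate_0ml"),
    "ringers_acetate_450ml": _crystalloid("ringers_acetate_450ml", 450.0),
    "ringers_acetate_900ml": _crystalloid("ringers_acetate_900ml", 900.0),
    "saline": _crystalloid("saline", observation=210.0),
    "ringers_lactate": _crystalloid("ringers_lactate", observation=210.0),
    "albumin": _colloid("albumin"),
    "autologous_plasma": _colloid("autologous_plasma"),
}

REFERENCE_FITS: dict[str, ReferenceFit] = {
    "ringers_acetate_0ml":   ReferenceFit(0.052, 4.86, 4.45, 0.49, 14.1, 13.3),
    "ringers_acetate_450ml": ReferenceFit(0.065, 3.88, 4.00, 0.57, 7.93, 7.52),
    "ringers_acetate_900ml": ReferenceFit(0.076, 3.27, 2.57, 0.38, 4.04, 3.84),
    "saline":                ReferenceFit(0.047, 5.56, 2.35, 0.46, 10.0, 9.62),
    "ringers_lactate":       ReferenceFit(0.069, 5.03, 2.39, 1.81, 17.6, 16.9),
    "albumin":               ReferenceFit(0.028, 3.94, 0.45, 0.05, 9.09, 8.73),
    "autologous_plasma":     ReferenceFit(0.147, 3.11, 0.34, 0.62, 6.49, 6.25),
}


def reference_params(name: str) -> ModelParams:
    """Reference ModelParams (ml, 1/min) for a named protocol fixture."""
    try:
        return REFERENCE_FITS[name].params()
    except KeyError:
        raise InputError(f"unknown protocol {name!r}; choose from "
                         f"{sorted(REFERENCE_FITS)}") from None


def schedule_from_protocol(spec: ProtocolSpec,
                           weight_kg: float | None = None) -> InputSchedule:
    """Build the piecewise-constant input schedule for a protocol.

    Infusion runs at dose·weight / infusion-time during the infusion phase,
    then zero.  Urine, when a total volume is given, is spread as a constant
    loss rate over the whole study duration — the same simplification the
    source protocols permit (only totals are reported).
    """
    weight = weight_kg if weight_kg is not None else spec.weight_kg
    if weight is None:
        weight = DEFAULT_WEIGHT_KG
    if weight <= 0:
        raise InputError("subject weight must be positive")
    total = spec.dose_ml_per_kg * weight
    u_rate = total / spec.infusion_time_min
    v_rate = ((spec.total_urine_ml / spec.duration_min)
              if spec.total_urine_ml else 0.0)
    return InputSchedule(
        breakpoints=np.array([0.0, spec.infusion_time_min]),
        u_rates=np.array([u_rate, 0.0]),
        v_rates=np.array([v_rate, v_rate]),
        duration=spec.duration_min)


def generate_synthetic_trace(params: ModelParams, schedule: InputSchedule,
                             T_S: float = 10.0, noise_sd: float = 0.0,
                             seed: int | np.random.Generator | None = None
                             ) -> VolumeTrace:
    """Forward-simulate a fractional blood-volume trace with measurement noise.

    Samples the exact response every ``T_S`` minutes (default 10 min, the
    reporting interval of the reference studies) and adds independent
    zero-mean Gaussian noise of standard deviation ``noise_sd`` to every
    sample.  ``noise_sd = 0`` returns the exact response.  Passing the same
    seed twice yields the identical trace.
    """
    if noise_sd < 0:
        raise InputError("noise_sd cannot be negative")
    n = int(np.floor(schedule.duration / T_S + 1e-9))
    times = np.arange(n + 1) * T_S
    vb = simulate_response(params, schedule, times).vb_frac.copy()
    if noise_sd > 0:
        rng = (seed if isinstance(seed, np.random.Generator)
               else np.random.default_rng(seed))
        vb = vb + rng.normal(0.0, noise_sd, size=vb.shape)
    return VolumeTrace(times, vb, sampling_interval=T_S)


def parameter_recovery_experiment(true_params: ModelParams,
                                  schedule: InputSchedule,
                                  T_S: float = 10.0,
                                  noise_sd: float = 0.005,
                                  replicates: int = 20,
                                  seed: int = 0,
                                  fit_options: FitOptions | None = None) -> dict:
    """Monte-Carlo assessment of how well fitting recovers known parameters.

    Generates ``replicates`` noisy traces from ``true_params``, refits each,
    and summarizes the signed relative errors per parameter.  Fully
    reproducible given ``seed`` (which also reseeds the optimizer's random
    starts per replicate).  Fit failures are counted, not raised.

    Returns a dict with per-parameter arrays of relative errors and summary
    statistics (relative bias, relative RMSE, median absolute relative error).
    """
    if replicates < 1:
        raise InputError("need at least one replicate")
    fit_options = fit_options or FitOptions()
    root = np.random.SeedSequence(seed)
    children = root.spawn(replicates)
    truth = {"alpha": true_params.alpha, "K": true_params.K,
             "V_B0": true_params.V_B0}
    rel_errors = {k: [] for k in truth}
    estimates = []
    n_failed = 0
    for child in children:
        rng = np.random.default_rng(child)
        trace = generate_synthetic_trace(true_params, schedule, T_S=T_S,
                                         noise_sd=noise_sd, seed=rng)
        opts = replace(fit_options,
                       seed=int(child.generate_state(1)[0] % (2 ** 31)))
        try:
            fit = fit_model(trace, schedule, opts)
        except Exception:
            n_failed += 1
            continue
        est = fit.params_star
        estimates.append(est)
        for name, true_val in truth.items():
            rel_errors[name].append((getattr(est, name) - true_val) / true_val)

    summary = {"n_replicates": replicates, "n_failed": n_failed,
               "noise_sd": noise_sd, "estimates": estimates,
               "relative_errors": {k: np.asarray(v)
                                   for k, v in rel_errors.items()}}
    for name, errs in rel_errors.items():
        errs = np.asarray(errs, dtype=float)
        if errs.size:
            summary[name] = {
                "relative_bias": float(np.mean(errs)),
                "relative_rmse": float(np.sqrt(np.mean(errs ** 2))),
                "median_abs_relative_error": float(np.median(np.abs(errs))),
            }
        else:
            summary[name] = {"relative_bias": np.nan, "relative_rmse": np.nan,
                             "median_abs_relative_error": np.nan}
    return summary
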