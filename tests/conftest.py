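import numpy as np
import pytest

from fluidshift import (InputSchedule, ModelParams, PROTOCOLS,
                        reference_params, schedule_from_protocol)


@pytest.fixture
def typical_params():
    """A crystalloid-like parameter set used across modules."""
    return ModelParams(alpha=2.0, K=0.05, V_B0=4000.0)


@pytest.fixture
def constant_infusion():
    """20 ml/min constant infusion, no loss, 60 min."""
    return InputSchedule.constant(20.0, 0.0, 60.0)


@pytest.fixture
def bolus_schedule():
    """1500 ml bolus over 30 min, then observation until 600 min."""
    return InputSchedule(np.array([0.0, 30.0]), np.array([50.0, 0.0]),
                         np.array([0.0, 0.0]), 600.0)


@pytest.fixture
def saline_truth():
    return reference_params("saline")


@pytest.fixture
def saline_schedule():
    return schedule_from_protocol(PROTOCOLS["saline"])


def analytic_constant_infusion(t, c, alpha, K):
    """Closed-form ΔV_B(t) for constant net input c from t = 0.

    Independent oracle: direct solution of the linear ODE system
    (derived separately from the simulator's segment propagation).
    """
    t = np.asarray(t, dtype=float)
    return (c * t / (1 + alpha)
            + c * alpha / (K * (1 + alpha)) * (1 - np.exp(-K * t)))
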