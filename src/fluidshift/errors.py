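"""Exception hierarchy shared across the package."""


class FluidShiftError(ValueError):
    """Base class for all domain errors raised by fluidshift."""


class ParameterDomainError(FluidShiftError):
    """A model parameter is outside its physically admissible domain."""


class ScheduleRangeError(FluidShiftError):
    """A query time falls outside the span of an input schedule."""


class InputError(FluidShiftError):
    """Malformed or inconsistent user input (files, grids, series)."""


class NonInformativeDataError(FluidShiftError):
    """The data carry no excitation, so the parameters are unidentifiable."""


class InadmissibleRegressionError(FluidShiftError):
    """The linear-regression estimate maps to inadmissible parameters."""


class OptimizationFailureError(FluidShiftError):
    """No optimizer start point converged; carries per-start diagnostics."""

    def __init__(self, message, diagnostics=None):
        super().__init__(message)
        self.diagnostics = diagnostics or []


class NormalizationError(FluidShiftError):
    """A normalization denominator (e.g. the trace mean) is zero."""
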