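"""Exception hierarchy.

``ValidationError`` covers bad inputs and configuration (CLI exit code 2);
``ConvergenceError`` covers numerical non-convergence (CLI exit code 3).
"""


class PermeapathError(Exception):
    """Base class for all package errors."""


class ValidationError(PermeapathError, ValueError):
    """Invalid input data, configuration, or arguments."""


class ConvergenceError(PermeapathError, RuntimeError):
    """An iterative solver failed to reach its tolerance."""

    def __init__(self, message: str, residual: float | None = None):
        super().__init__(message)
        self.residual = residual


class CoverageError(ValidationError):
    """A profile does not cover the interval an operation needs."""


class DegenerateSeriesError(ValidationError):
    """A time series has zero variance and cannot be analysed."""


class PipelineError(PermeapathError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage
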