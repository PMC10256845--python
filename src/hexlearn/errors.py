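"""Exception hierarchy shared across the pipeline."""


class HexlearnError(Exception):
    """Base class for all package errors."""


class InvalidDesignError(HexlearnError):
    """Task or questionnaire design violates a structural constraint."""


class ConfigurationError(HexlearnError):
    """Unknown model identifier or malformed configuration."""


class NumericalError(HexlearnError):
    """Non-finite intermediate quantity; message names the trial/context."""


class InsufficientDataError(HexlearnError):
    """Too few usable observations to estimate anything."""


class OptimizationFailureError(HexlearnError):
    """No optimizer start converged; carries diagnostics."""

    def __init__(self, message: str, diagnostics=None):
        super().__init__(message)
        self.diagnostics = diagnostics


class ConvergenceError(HexlearnError):
    """Iterative scheme failed to converge; carries the iteration trace."""

    def __init__(self, message: str, trace=None):
        super().__init__(message)
        self.trace = trace


class DegenerateDataError(HexlearnError):
    """Zero-variance or otherwise degenerate input to a statistic."""


class EstimationError(HexlearnError):
    """Structural-model estimation did not converge."""


class ValidationError(HexlearnError):
    """Input table failed schema/range/alignment checks."""

    def __init__(self, message: str, items=None):
        super().__init__(message)
        self.items = list(items) if items is not None else []
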