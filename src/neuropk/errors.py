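"""Exception hierarchy shared across the package."""

from __future__ import annotations


class NeuropkError(Exception):
    """Base class for all package errors."""


class InvalidInputError(NeuropkError, ValueError):
    """A physical quantity is outside its admissible domain.

    The message names the offending field.
    """


class ConfigurationError(NeuropkError):
    """A model cannot be assembled from the given pieces."""


class ValidationError(NeuropkError):
    """Config validation failed; ``problems`` lists every violation found."""

    def __init__(self, problems: list[str]):
        self.problems = list(problems)
        super().__init__("invalid configuration: " + "; ".join(self.problems))


class IntegrationError(NeuropkError):
    """The ODE solver failed or produced an inconsistent trajectory."""


class CalibrationError(NeuropkError):
    """Barrier calibration did not converge; carries the residual trace."""

    def __init__(self, message: str, residual_trace=None):
        self.residual_trace = residual_trace
        super().__init__(message)
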