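"""Exception hierarchy for the nestedwell package.

Every error raised by the library derives from :class:`NestedWellError` so
callers (and the CLI) can catch domain failures without masking bugs.
"""


class NestedWellError(Exception):
    """Base class for all nestedwell errors."""


class InvalidParameterError(NestedWellError, ValueError):
    """A physical parameter is out of its admissible range."""


class NonphysicalSelectivityError(InvalidParameterError):
    """Specific Kd is not smaller than the nonspecific reference K1.

    The nested-well picture requires Kd < K1: adding an inner (specific)
    well can only strengthen the overall binding.
    """


class ScheduleError(NestedWellError, ValueError):
    """Injection schedule is malformed (non-monotone times, length mismatch)."""


class DataError(NestedWellError, ValueError):
    """Input data insufficient or inconsistent for the requested fit."""


class FitError(NestedWellError, RuntimeError):
    """Nonlinear least squares failed to converge; carries diagnostics."""

    def __init__(self, message: str, diagnostics: dict | None = None):
        super().__init__(message)
        self.diagnostics = diagnostics or {}


class NoBindingSignalError(DataError):
    """Fitted association rate is zero or negative: no binding signal."""


class FormatError(NestedWellError, ValueError):
    """A file does not conform to the documented CSV/JSON layout."""


class ConsistencyError(NestedWellError, ValueError):
    """Trace data and manifest/schedule disagree."""


class ConfigError(NestedWellError, ValueError):
    """Analysis configuration contains unknown or invalid settings."""
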