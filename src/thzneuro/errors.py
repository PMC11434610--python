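"""Exception hierarchy shared across the package."""


class ThzNeuroError(Exception):
    """Base class for all package-specific errors."""


class IntegrationError(ThzNeuroError):
    """Numerical integration produced a non-finite state.

    Carries ``t_ms``, the simulation time at which divergence was first
    detected.
    """

    def __init__(self, t_ms: float, message: str | None = None):
        self.t_ms = t_ms
        super().__init__(message or f"integration diverged at t = {t_ms:.3f} ms")


class BracketError(ThzNeuroError):
    """A search bracket did not contain the sought transition."""


class FitError(ThzNeuroError):
    """A curve fit failed to converge; carries residual diagnostics."""

    def __init__(self, message: str, residuals=None):
        self.residuals = residuals
        super().__init__(message)


class MetricUndefinedError(ThzNeuroError):
    """A waveform metric is undefined for the given trace (e.g. peak below baseline)."""


class ShapeError(ThzNeuroError):
    """A waveform violates the expected trough-then-peak shape."""


class SchemaError(ThzNeuroError):
    """A data file does not match its documented column schema."""


class EmptyInputError(ThzNeuroError):
    """An input file or array was unexpectedly empty."""


class InsufficientDataError(ThzNeuroError):
    """Not enough qualifying data points for the requested analysis."""


class ConfigError(ThzNeuroError):
    """Configuration failed validation; message names the offending field."""
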