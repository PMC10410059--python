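"""Exception hierarchy shared across the package."""


class Psen1TrajError(Exception):
    """Base class for all package-specific errors."""


class ConfigError(Psen1TrajError, ValueError):
    """Invalid simulation or analysis configuration."""


class InputError(Psen1TrajError, ValueError):
    """Invalid user-supplied value (codon, volume, probability, ...)."""


class ValidationError(Psen1TrajError, ValueError):
    """A table failed schema or key validation."""


class DegenerateKnotsError(Psen1TrajError, ValueError):
    """Spline knots collapsed (ties); a linear EYO form should be used instead."""


class SamplingError(Psen1TrajError, RuntimeError):
    """Posterior sampling failed; carries the diagnostics that triggered it."""

    def __init__(self, message, diagnostics=None):
        super().__init__(message)
        self.diagnostics = diagnostics
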