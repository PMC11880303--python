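"""Exception hierarchy shared across the package."""


class AggphotError(Exception):
    """Base class for all package errors."""


class InputError(AggphotError):
    """Malformed or unreadable input data."""


class DegenerateInputError(AggphotError):
    """Input is structurally valid but degenerate for the requested operation."""


class ConfigError(AggphotError):
    """Invalid configuration value."""


class FitError(AggphotError):
    """Nonlinear fit failed to converge.

    Carries ``best_residual`` when a partial result exists.
    """

    def __init__(self, message, best_residual=None):
        super().__init__(message)
        self.best_residual = best_residual
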