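"""Exception hierarchy shared across the package."""


class PapsimError(Exception):
    """Base class for all package errors."""


class ConfigurationError(PapsimError):
    """Infeasible or inconsistent configuration (geometry, scheme, simulation)."""


class InputError(PapsimError):
    """Invalid or degenerate input data."""


class FitError(PapsimError):
    """A model fit failed or is unidentifiable."""
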