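"""Exception types shared across the package."""


class StochzymeError(Exception):
    """Base class for all package errors."""


class InvalidParameterError(StochzymeError, ValueError):
    """A distribution or scheme parameter is outside its admissible range."""


class NumericalFailureError(StochzymeError, RuntimeError):
    """A quadrature or root-finding step failed to converge."""


class UnsupportedModeError(StochzymeError, ValueError):
    """Operation called on an inhibition mode it is not defined for."""


class UnsupportedInputError(StochzymeError, ValueError):
    """Operation called with an input outside its stated assumptions."""


class ConfigError(StochzymeError, ValueError):
    """Scenario configuration is malformed."""
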