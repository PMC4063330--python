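"""Exception hierarchy shared across the package."""


class ScalarTimeError(Exception):
    """Base class for all package-specific errors."""


class ParameterError(ScalarTimeError, ValueError):
    """A model or configuration parameter is invalid (wrong sign, range...)."""


class DegenerateNoiseError(ParameterError):
    """Raised when rho = 1 (proportional noise): the log-power exponent
    n = 1/(1-rho) diverges and the power-law closed form must be used."""


class DomainError(ScalarTimeError, ValueError):
    """A time lies outside a rate function's region of validity."""


class IntegrationError(ScalarTimeError, RuntimeError):
    """The numerical ODE solver failed (step underflow, event violation)."""


class InsufficientDataError(ScalarTimeError, ValueError):
    """Too few uncensored trials / ensembles / points for the statistic."""


class ResidualTooLargeError(ScalarTimeError, RuntimeError):
    """The truncated first-crossing distribution leaves too much probability
    mass beyond the last bin for moments to be trustworthy."""


class DivergenceError(ScalarTimeError, RuntimeError):
    """The learned threshold escaped its admissible range."""
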