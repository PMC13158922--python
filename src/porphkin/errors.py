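"""Exception types shared across the package."""


class PorphkinError(Exception):
    """Base class for package errors."""


class InvalidInputError(PorphkinError, ValueError):
    """Raised when inputs violate a documented precondition."""


class ConfigurationError(PorphkinError, ValueError):
    """Raised when options are internally inconsistent (e.g. extended
    model evaluation without a k4)."""


class IntegrationFailure(PorphkinError, RuntimeError):
    """ODE solver did not produce a valid trajectory.

    Carries solver diagnostics in ``args`` so callers can log or
    penalise instead of aborting a whole multistart sweep.
    """


class FitFailure(PorphkinError, RuntimeError):
    """Every multistart attempt failed to converge."""


class BandFailure(PorphkinError, RuntimeError):
    """Too many Monte Carlo draws failed to integrate."""


class ParseError(PorphkinError, ValueError):
    """Dataset file is malformed; message names the offending rows."""
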