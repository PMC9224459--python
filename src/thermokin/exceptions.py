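"""Exception hierarchy for thermokin.

All package-specific errors derive from :class:`ThermokinError` so callers can
catch the whole family with one clause. The distinction between a
configuration problem (unknown model id, missing parameter), a mathematical
domain problem (nonpositive rate, invalid nth-order base) and an input-data
problem (bad table, too few observations) mirrors how the errors arise.
"""


class ThermokinError(Exception):
    """Base class for all thermokin errors."""


class ConfigurationError(ThermokinError):
    """Unknown model id, missing/invalid parameter set, bad options."""


class DomainError(ThermokinError, ValueError):
    """A quantity lies outside the mathematical domain of the operation."""


class SingularParameterizationError(DomainError):
    """A parameter combination makes the model expression singular
    (e.g. the series-type model with k1 == k2)."""


class InputError(ThermokinError, ValueError):
    """Malformed or insufficient input data."""


class DegreesOfFreedomError(InputError):
    """Fewer observations than parameters + 1."""
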