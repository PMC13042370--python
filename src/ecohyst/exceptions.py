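"""Exception hierarchy.

All errors derive from :class:`EcohystError` so callers can catch the
package's failures with a single except clause; each subclass also derives
from the closest builtin (``ValueError``) for interoperability.
"""


class EcohystError(ValueError):
    """Base class for all errors raised by ecohyst."""


class ParameterError(EcohystError):
    """Invalid model parameters (e.g. C0 >= C1, negative K)."""


class DomainError(EcohystError):
    """A state or driver value outside the mathematical domain of the model."""


class RegimeError(EcohystError):
    """An operation requiring hysteresis was attempted in a non-hysteretic regime."""


class RangeError(EcohystError):
    """A driver value outside the valid range of the requested branch."""


class DegenerateError(EcohystError):
    """A transform or alignment could not be built (zero spread, singular system)."""


class DataError(EcohystError):
    """A dataset violates the structural requirements of an operation."""


class SchemaError(DataError):
    """An input table is missing a required column or has a malformed header."""


class ParseError(DataError):
    """An input table cell could not be parsed; carries the offending line."""


class NoTransitionError(DataError):
    """No abrupt state jump was found in a one-sided sweep."""


class FitError(EcohystError):
    """Parameter estimation failed (e.g. the loss is infinite everywhere)."""
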