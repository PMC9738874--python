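"""Exception hierarchy.

All domain errors derive from :class:`RenalPetError` so callers can catch the
package's failures with one clause; the ``ValueError``/``RuntimeError`` mixins
keep them catchable by generic code.
"""


class RenalPetError(Exception):
    """Base class for all renalpet errors."""


class InvalidParameterError(RenalPetError, ValueError):
    """A model/kinetic parameter or argument violates its domain constraints."""


class DegenerateInputError(RenalPetError, ValueError):
    """Input data carry no usable signal (e.g. an all-zero curve)."""


class InsufficientDataError(RenalPetError, ValueError):
    """Too few data points for the requested operation."""


class FitError(RenalPetError, RuntimeError):
    """A model fit could not be performed on the given data."""
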