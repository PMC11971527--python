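"""Exception hierarchy for hopffit.

Every error raised on a user-facing code path derives from :class:`HopffitError`
so callers can catch the package's failures with a single ``except``.
"""


class HopffitError(Exception):
    """Base class for all hopffit errors."""


class InvalidConfigurationError(HopffitError, ValueError):
    """A configuration value is out of range or internally inconsistent."""


class InvalidInputError(HopffitError, ValueError):
    """Input data violate a precondition (shape, sign, emptiness ...)."""


class DegenerateInputError(HopffitError, ValueError):
    """An operation is undefined for this input (zero variance, zero vector ...)."""


class UndefinedFeatureError(HopffitError, ValueError):
    """A spectral feature is undefined (e.g. zero total power) for some region."""


class NumericalInstabilityError(HopffitError, ArithmeticError):
    """The integrator blew up; message names the offending step."""
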