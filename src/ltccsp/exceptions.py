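"""Exception hierarchy shared across the package."""


class LtccspError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(LtccspError, ValueError):
    """Input data violates a structural contract (shape, labels, finiteness)."""


class ParameterError(ValidationError):
    """A parameter is outside its admissible range (tau < 1, sigma <= 0, ...)."""


class DegenerateInputError(ValidationError):
    """Input is structurally valid but numerically degenerate (all-zero trial,
    zero weighted trace, sigma0 = 0)."""


class ConditioningError(LtccspError):
    """The composite covariance R_X + R_Y is rank deficient beyond tolerance.

    Remove linearly dependent channels or enable an explicit ridge.
    """


class DegenerateFeatureError(LtccspError):
    """A spatial filter produced a zero-variance projection; no log-variance
    feature can be formed."""
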