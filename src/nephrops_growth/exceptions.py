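"""Domain errors raised by the estimation and simulation routines."""


class NephropsGrowthError(Exception):
    """Base class for all package-specific errors."""


class InvalidParameterError(NephropsGrowthError, ValueError):
    """A parameter violates its domain (e.g. L0 >= L_inf, Z/k <= 0)."""


class EmptyTailError(NephropsGrowthError, ValueError):
    """No observations at or above the requested cutoff length."""


class DegenerateFitError(NephropsGrowthError, ValueError):
    """A regression cannot yield a valid estimate (slope out of range,
    too few points, or collinear abscissae)."""


class SchemaError(NephropsGrowthError, ValueError):
    """An input file is missing a required column or is malformed."""
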