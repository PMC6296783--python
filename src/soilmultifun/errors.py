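"""Exception hierarchy shared across the package.

Every error raised by soilmultifun derives from :class:`SoilMultifunError`,
so callers can catch one type at a pipeline boundary.
"""


class SoilMultifunError(Exception):
    """Base class for all soilmultifun errors."""


class SchemaError(SoilMultifunError):
    """A table does not match its declared schema (missing column,
    duplicate key, non-numeric cell); the message cites the location."""


class InvalidInputError(SoilMultifunError):
    """A value violates a documented precondition (e.g. negative cover)."""


class UndefinedCommunityError(SoilMultifunError):
    """An index was requested for a community with zero total abundance."""


class DegenerateTraitError(SoilMultifunError):
    """A trait column has zero range, so Gower normalisation is undefined."""


class DegenerateFunctionError(SoilMultifunError):
    """A function is constant across plots, so min-max standardisation
    is undefined."""


class InvalidThresholdError(SoilMultifunError):
    """Threshold outside the (0, 100] percent range."""


class DegenerateDesignError(SoilMultifunError):
    """The design cannot support the requested fit (e.g. a regression on
    richness with fewer than two distinct richness levels)."""


class IncompleteSeriesError(SoilMultifunError):
    """A respiration series is shorter than the computation's window."""


class DegenerateSampleError(SoilMultifunError):
    """A wet-sieving measurement whose coarse matter exhausts the sample."""


class NegativeFractionError(SoilMultifunError):
    """Water-stable fraction below the coarse-matter mass."""


class AliasingError(SoilMultifunError):
    """The coded model matrix is rank deficient; confounded terms are named."""


class InsufficientDataError(SoilMultifunError):
    """Too few observations to identify the requested model."""


class DataError(SoilMultifunError):
    """Input data violate a distributional requirement (e.g. a sample
    covariance matrix that is not positive definite)."""
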