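"""Exception hierarchy shared across the package."""


class SomnoclockError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(SomnoclockError, ValueError):
    """An input violates a documented invariant."""


class MissingDayError(SomnoclockError):
    """A per-day operation was applied to a day flagged as missing."""


class NoDataError(SomnoclockError):
    """Every record needed for a summary is missing or absent."""


class InsufficientDataError(SomnoclockError):
    """Too few valid observations (e.g. zero valid epoch pairs) to score."""


class DegenerateInputError(SomnoclockError):
    """Input lacks the variation a fit requires (e.g. too few distinct values)."""


class UnsplittableTieError(SomnoclockError):
    """A median/quantile split is undefined because tied values straddle the boundary."""
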