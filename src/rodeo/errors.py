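"""Exception hierarchy shared across the package."""


class RodeoError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(RodeoError, ValueError):
    """An input value or matrix violates a documented invariant."""


class RankDeficiencyError(RodeoError, ValueError):
    """The regression design matrix does not have full column rank."""

    def __init__(self, message: str, collinear: tuple[int, ...] = ()):
        super().__init__(message)
        self.collinear = collinear


class UnderdeterminedError(RodeoError, ValueError):
    """Fewer observations than predictors: the system has no unique solution."""


class AlignmentError(RodeoError, ValueError):
    """Identifier sets of two matrices that must be aligned do not match."""


class InsufficientDataError(RodeoError, ValueError):
    """Too few data points for the requested statistic to be defined."""


class ParseError(RodeoError, ValueError):
    """A delimited matrix file could not be parsed."""
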