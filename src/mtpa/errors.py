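"""Exception types shared across the package."""


class MtpaError(Exception):
    """Base class for package-specific errors."""


class ConstantSeriesError(MtpaError, ValueError):
    """A series with zero variance was passed where variation is required."""


class RankDeficientError(MtpaError, ValueError):
    """A regression design matrix is rank deficient.

    ``columns`` names the offending columns (those that are linearly
    dependent on the columns preceding them).
    """

    def __init__(self, columns):
        self.columns = list(columns)
        super().__init__(f"design matrix is rank deficient; offending columns: {self.columns}")


class NonUniqueSolutionError(MtpaError, ValueError):
    """The optimisation problem has no unique minimizer."""


class UndefinedResultError(MtpaError, ValueError):
    """The requested quantity is mathematically undefined for this input."""
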