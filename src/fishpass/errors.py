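"""Exception hierarchy shared across the package."""


class FishpassError(Exception):
    """Base class for package errors."""


class ConfigurationError(FishpassError, ValueError):
    """Invalid user-supplied configuration (negative lag, bad factor, ...)."""


class DataError(FishpassError, ValueError):
    """Input data violates a documented precondition."""


class DegenerateCovariateError(DataError):
    """A continuous covariate has zero variance and cannot be standardized."""


class ConvergenceError(FishpassError, RuntimeError):
    """An iterative fit failed to converge (separation, monotone likelihood)."""


class RankDeficiencyError(DataError):
    """Design matrix is rank deficient; names the collinear columns."""

    def __init__(self, columns):
        self.columns = list(columns)
        super().__init__(
            "design matrix is rank deficient; collinear covariates: "
            + ", ".join(self.columns)
        )
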