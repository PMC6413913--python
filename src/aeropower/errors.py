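"""Exception hierarchy.

Schema problems (malformed files, unknown tags, missing columns) map to CLI
exit code 2; computation problems (degenerate inputs, singular designs) map
to exit code 3.
"""


class AeropowerError(Exception):
    """Base class for all package errors."""

    exit_code = 3


class SchemaError(AeropowerError):
    """A file or object does not conform to its documented schema."""

    exit_code = 2


class DataValidationError(AeropowerError):
    """Input data violate a documented precondition."""

    exit_code = 2


class ComputationError(AeropowerError):
    """A numerical operation is undefined for the given input."""

    exit_code = 3


class InvalidProtocolError(DataValidationError):
    """Treadmill protocol parameters are inconsistent (e.g. non-positive increments)."""


class InvalidShapeError(DataValidationError):
    """Wingate power-curve parameters cannot yield a positive power curve."""


class CohortTooSmallError(DataValidationError):
    """Cohort too small for downstream train/test/validation splitting."""


class InsufficientDataError(DataValidationError):
    """Too few breaths (or too little signal) to run an operation."""


class ZeroVarianceError(ComputationError):
    """A feature column has zero variance; standardization is undefined."""

    def __init__(self, columns):
        self.columns = list(columns)
        super().__init__(f"zero-variance column(s): {', '.join(self.columns)}")


class ConstantColumnError(ComputationError):
    """A feature column is constant; its rank correlation is undefined."""

    def __init__(self, columns):
        self.columns = list(columns)
        super().__init__(f"constant column(s), Spearman undefined: {', '.join(self.columns)}")


class RankDeficiencyError(ComputationError):
    """The OLS design matrix is rank deficient."""

    def __init__(self, features):
        self.features = list(features)
        super().__init__(f"rank-deficient design; offending feature(s): {', '.join(self.features)}")


class StratificationError(DataValidationError):
    """Not enough subjects to populate every stratum of a stratified split."""


class UndefinedAdjustmentError(ComputationError):
    """Adjusted R-squared is undefined (n <= p + 1)."""


class MissingFeatureError(SchemaError):
    """A prediction equation references a feature absent from the input."""

    def __init__(self, features):
        self.features = list(features)
        super().__init__(f"missing feature(s): {', '.join(self.features)}")


class UndefinedModularityError(ComputationError):
    """Modularity is undefined for a network with zero total edge weight."""
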