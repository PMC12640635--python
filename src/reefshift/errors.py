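"""Exception hierarchy for the reefshift pipeline."""


class ReefshiftError(Exception):
    """Base class for all package errors."""


class ConfigurationError(ReefshiftError):
    """Invalid simulation or pipeline configuration."""


class ValidationError(ReefshiftError):
    """Input table failed schema or range validation.

    Carries optional row/column context so CLI users can locate the
    offending cell.
    """

    def __init__(self, message: str, row=None, column=None):
        if row is not None or column is not None:
            message = f"{message} (row={row}, column={column})"
        super().__init__(message)
        self.row = row
        self.column = column


class ClimatologyError(ReefshiftError):
    """Climatology cannot be computed from the supplied series."""


class ImputationError(ReefshiftError):
    """A variable is missing everywhere; imputation is impossible."""


class InferenceError(ReefshiftError):
    """Group structure insufficient for permutation inference."""


class DiversityError(ReefshiftError):
    """Diversity statistic undefined for the supplied counts."""


class DecompositionError(ReefshiftError):
    """PCA / standardization cannot proceed."""


class FitError(ReefshiftError):
    """Regression fit is degenerate (e.g. zero predictor variance)."""
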