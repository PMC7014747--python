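"""Exception hierarchy shared across the package."""


class CytoreduxError(Exception):
    """Base class for all package-specific errors."""


class SchemaError(CytoreduxError):
    """A cohort table is structurally invalid (missing/duplicate columns)."""


class RowValidationError(CytoreduxError):
    """A single row failed validation.

    Attributes
    ----------
    row : int or None
        Zero-based data-row index (header excluded), when known.
    field : str or None
        Name of the offending field, when known.
    """

    def __init__(self, message, row=None, field=None):
        super().__init__(message)
        self.row = row
        self.field = field


class CohortError(CytoreduxError):
    """A cohort-level invariant is violated (duplicate ids, one-class data)."""


class SeparationError(CytoreduxError):
    """Logistic fit diverged: the data are (quasi-)completely separated."""


class ConvergenceError(CytoreduxError):
    """Iterative fit failed to converge within the iteration budget."""


class PipelineStageError(CytoreduxError):
    """A pipeline stage failed; wraps the stage name and the causal error."""

    def __init__(self, stage, cause):
        super().__init__(f"stage '{stage}' failed: {cause}")
        self.stage = stage
        self.cause = cause
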