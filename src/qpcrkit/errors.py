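"""Exception hierarchy shared by all qpcrkit stages."""


class QpcrError(Exception):
    """Base class for all qpcrkit errors."""


class SchemaError(QpcrError):
    """Input table is missing a required column or has an unusable layout."""


class ValidationError(QpcrError):
    """Input records violate table invariants.

    Carries the full report so callers can show every problem at once.
    """

    def __init__(self, message, report=None):
        super().__init__(message)
        self.report = report


class InsufficientDataError(QpcrError):
    """Too few usable observations for the requested computation."""


class DegenerateDesignError(QpcrError):
    """Regression design has no variance in the predictor."""


class StageError(QpcrError):
    """A pipeline stage failed its preconditions."""
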