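"""Exception hierarchy shared across the assessment pipeline."""


class LenAssessError(Exception):
    """Base class for all package errors."""


class ValidationError(LenAssessError):
    """Input records or configuration violate a precondition."""


class InsufficientDataError(LenAssessError):
    """Too few records (or too little structure) to attempt a fit."""


class DomainError(LenAssessError, ValueError):
    """An argument lies outside the mathematical domain of a formula."""


class FitError(LenAssessError):
    """Nonlinear fit failed to converge; carries the best attempt found.

    Attributes
    ----------
    params : tuple | None
        Best parameter vector found across starts.
    rss : float | None
        Residual sum of squares of that attempt.
    """

    def __init__(self, message, params=None, rss=None):
        super().__init__(message)
        self.params = params
        self.rss = rss


class StageError(LenAssessError):
    """A pipeline stage failed; names the stage so partial output is traceable."""

    def __init__(self, stage, message):
        super().__init__(f"stage '{stage}': {message}")
        self.stage = stage
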