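"""Exception hierarchy shared across the package."""


class RdocPhenoError(Exception):
    """Base class for all package errors."""


class FormatError(RdocPhenoError):
    """A file does not match its declared on-disk format (bad header, wrong columns)."""


class ValidationError(RdocPhenoError):
    """Structurally well-formed input violates a domain invariant."""

    def __init__(self, message: str, rows: list | None = None):
        super().__init__(message)
        self.rows = rows or []


class PipelineError(RdocPhenoError):
    """A document failed inside the text pipeline; carries the note id."""

    def __init__(self, message: str, note_id: str | None = None):
        super().__init__(message)
        self.note_id = note_id


class ModelFitError(RdocPhenoError):
    """A statistical model could not be fit (separation, zero variance, collinearity)."""
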