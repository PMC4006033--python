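"""Exception hierarchy."""


class SaglocError(Exception):
    """Base class for all package errors."""


class InvalidParameterError(SaglocError, ValueError):
    """A parameter value is outside its admissible range."""


class FormatError(SaglocError, ValueError):
    """An external file does not conform to the expected format."""


class DataValidationError(SaglocError, ValueError):
    """Tabular input failed validation.

    Attributes
    ----------
    row : int or None
        Zero-based index of the offending data row, when known.
    """

    def __init__(self, message: str, row: int | None = None):
        super().__init__(message)
        self.row = row
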