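"""Exception hierarchy shared across the package."""


class ArrayQtlError(Exception):
    """Base class for all package-specific errors."""


class InputError(ArrayQtlError):
    """A required input file is missing or unreadable."""


class ParseError(ArrayQtlError):
    """A record in an input file could not be interpreted.

    Carries the offending line number when known, so the user can find
    the record in the original file.
    """

    def __init__(self, message: str, line_number: int | None = None):
        if line_number is not None:
            message = f"line {line_number}: {message}"
        super().__init__(message)
        self.line_number = line_number


class IntegrityError(ArrayQtlError):
    """Cross-references within an annotation are inconsistent."""
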