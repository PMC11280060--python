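"""Exception hierarchy shared across the package."""


class ResinateError(Exception):
    """Base class for all package errors."""


class ContractError(ValueError, ResinateError):
    """An argument violates a documented precondition."""


class ParseError(ResinateError):
    """A text input could not be parsed; carries the offending line number."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"{message} (line {line})"
        super().__init__(message)


class OutOfRangeError(ContractError):
    """A ppm value or window falls outside the spectrum axis."""


class InvalidSpectrumError(ResinateError):
    """Fewer than two points, mismatched lengths, or a non-monotone axis."""
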