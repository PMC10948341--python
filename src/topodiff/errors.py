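"""Exception hierarchy.

``TopoDiffError`` is the base for everything the package raises on bad
input, so callers (and the CLI) can distinguish validation failures from
genuine bugs.
"""


class TopoDiffError(Exception):
    """Base class for all topodiff errors."""


class ValidationError(TopoDiffError, ValueError):
    """Input violates a documented precondition or schema."""


class ParseError(TopoDiffError, ValueError):
    """A file could not be parsed; carries the offending line number."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)
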