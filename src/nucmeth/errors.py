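"""Exception types shared across the toolkit."""


class NucmethError(Exception):
    """Base class for all nucmeth errors."""


class InvalidConfigError(NucmethError, ValueError):
    """A configuration or parameter value violates its contract."""


class ParseError(NucmethError, ValueError):
    """A text input file could not be parsed."""

    def __init__(self, message: str, line_number: int | None = None):
        if line_number is not None:
            message = f"line {line_number}: {message}"
        super().__init__(message)
        self.line_number = line_number


class ProfileMismatchError(NucmethError, ValueError):
    """Two profiles with incompatible bins/contexts were combined."""


class DependencyError(NucmethError, RuntimeError):
    """A pipeline stage is missing an upstream input."""
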