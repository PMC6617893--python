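"""Exception types shared across the package."""


class SpacerGraphsError(Exception):
    """Base class for all package-specific errors."""


class ParseError(SpacerGraphsError, ValueError):
    """A malformed input file; carries the offending line number when known."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


class ValidationError(SpacerGraphsError, ValueError):
    """Structurally valid input that violates a dataset-level constraint."""


class DomainError(SpacerGraphsError, ValueError):
    """An argument outside the mathematical domain of an operation."""


class UndefinedScoreError(SpacerGraphsError, ValueError):
    """A statistic that cannot be computed from the given data (never silently 0)."""
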