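"""Exception hierarchy for the pulsechase pipeline.

Every error raised by the package derives from :class:`PulsechaseError`, so
callers (and the CLI) can catch pipeline problems without masking genuine
bugs. Parse/validation errors carry the 1-based file row where the problem
was found.
"""

from __future__ import annotations


class PulsechaseError(Exception):
    """Base class for all pipeline errors."""


class SchemaError(PulsechaseError):
    """Input table is missing required columns or has a malformed header."""


class ParseError(PulsechaseError):
    """A field could not be parsed into its declared type."""

    def __init__(self, message: str, row: int | None = None, column: str | None = None):
        self.row = row
        self.column = column
        loc = []
        if row is not None:
            loc.append(f"row {row}")
        if column is not None:
            loc.append(f"column {column!r}")
        suffix = f" ({', '.join(loc)})" if loc else ""
        super().__init__(message + suffix)


class ValidationError(PulsechaseError):
    """A parsed value violates a domain invariant (e.g. negative area)."""

    def __init__(self, message: str, row: int | None = None):
        self.row = row
        suffix = f" (row {row})" if row is not None else ""
        super().__init__(message + suffix)


class DuplicateKeyError(PulsechaseError):
    """Two rows share a key that must be unique within one table."""


class ConfigError(PulsechaseError):
    """A simulation or pipeline configuration is invalid."""


class InsufficientDataError(PulsechaseError):
    """Not enough observations to compute the requested quantity."""


class UndefinedEnrichmentError(PulsechaseError):
    """Heavy and light areas are both zero; enrichment is undefined."""


class BaitMissingError(PulsechaseError):
    """The bait protein is absent (or has zero counts) in an IP run."""


class StageError(PulsechaseError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: BaseException):
        self.stage = stage
        self.cause = cause
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
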