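"""Exception hierarchy for the AMU quantification pipeline."""

from __future__ import annotations


class AmuError(Exception):
    """Base class for all package errors."""


class CatalogueError(AmuError):
    """Problem in the drug-product catalogue, DDD registry or WHO map."""


class ValidationError(AmuError):
    """A record or file violates its schema or an invariant.

    ``row`` carries the 1-based data-row number when the error originates
    from a delimited file.
    """

    def __init__(self, message: str, *, row: int | None = None) -> None:
        self.row = row
        if row is not None:
            message = f"row {row}: {message}"
        super().__init__(message)


class MetricsError(AmuError):
    """A dose-metric computation received a degenerate input."""
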