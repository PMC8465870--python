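"""Exception hierarchy for swaysom.

All errors derive from :class:`SwaySomError` so callers can catch the
package's failures with a single except clause; each subclass also derives
from the closest builtin (ValueError) so sloppy callers still fail loudly.
"""


class SwaySomError(Exception):
    """Base class for all swaysom errors."""


class InvalidArgumentError(SwaySomError, ValueError):
    """An argument violates a documented precondition."""


class DomainError(SwaySomError, ValueError):
    """Input violates the physical/geometric domain (e.g. |d| >= L)."""


class DegenerateSampleError(SwaySomError, ValueError):
    """A sample makes the computation undefined (e.g. zero resultant)."""

    def __init__(self, message: str, index: int | None = None):
        super().__init__(message)
        self.index = index


class InsufficientDataError(SwaySomError, ValueError):
    """Too few samples for the requested operation."""


class EmptyResultError(SwaySomError, ValueError):
    """An operation produced no result (e.g. no active prototypes)."""


class DegenerateClusteringError(SwaySomError, ValueError):
    """Clustering configuration is degenerate (e.g. coincident centroids)."""


class DataError(SwaySomError):
    """Input data files/tables are malformed or incomplete (CLI exit 1)."""


class ConfigError(SwaySomError):
    """Pipeline configuration is invalid (CLI exit 2)."""
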