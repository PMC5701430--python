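"""Exception hierarchy shared across the package."""


class PopsegError(Exception):
    """Base class for all package-specific errors."""


class CatalogError(PopsegError):
    """Malformed or inconsistent condition catalog."""


class SchemaError(PopsegError):
    """An input table is missing columns or cannot be parsed at all."""


class RowError(PopsegError):
    """One or more rows of an input table failed validation (strict mode).

    Carries the per-row report as ``errors``: a list of
    ``(row_number, message)`` pairs, row numbers counted from 1 for the
    first data row after the header.
    """

    def __init__(self, message: str, errors=None):
        super().__init__(message)
        self.errors = list(errors or [])


class ConfigurationError(PopsegError):
    """Invalid or infeasible segmentation / generator configuration."""


class ConsistencyError(PopsegError):
    """Cross-table or cross-object references do not line up."""
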