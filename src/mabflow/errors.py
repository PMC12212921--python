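"""Exception hierarchy for the pipeline.

Every error raised on purpose by this package derives from :class:`MabflowError`,
so callers (and the CLI) can distinguish pipeline validation failures from bugs.
"""


class MabflowError(Exception):
    """Base class for all pipeline errors."""


class AddressingError(MabflowError):
    """A well label, linear index or quadrant is malformed or out of range."""


class InputValidationError(MabflowError):
    """A user-supplied argument violates its precondition (CLI usage errors)."""


class HeaderValidationError(MabflowError):
    """A file header does not match the configured expectation.

    Carries ``missing`` and ``extra`` column lists so reports can name the
    offending columns.
    """

    def __init__(self, message: str, missing=(), extra=()):
        super().__init__(message)
        self.missing = list(missing)
        self.extra = list(extra)


class RowValidationError(MabflowError):
    """One or more data rows failed validation; carries a per-row report."""

    def __init__(self, message: str, row_errors=()):
        super().__init__(message)
        self.row_errors = list(row_errors)


class ReferentialIntegrityError(MabflowError):
    """A foreign-key value does not resolve to an existing record."""


class UnknownTableError(MabflowError):
    """A table name is not part of the active schema."""


class UnknownRecordError(MabflowError):
    """A record ID does not exist in the store."""


class SchemaError(MabflowError):
    """A schema definition is internally inconsistent."""


class PrimerLookupError(MabflowError):
    """No primer in the registry matches an allele call."""

    def __init__(self, message: str, allele: str | None = None):
        super().__init__(message)
        self.allele = allele


class RegistryError(MabflowError):
    """The primer registry file is malformed (duplicate names, missing keys)."""


class DuplicateSampleError(MabflowError):
    """A sample was enqueued twice onto the same store list."""


class CountMismatchError(MabflowError):
    """Sample counts disagree with the declared expectation."""


class LineageError(MabflowError):
    """A record's ancestry is incomplete for the requested operation."""


class ConfigError(MabflowError):
    """The configuration file is invalid (duplicate or missing keys)."""
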