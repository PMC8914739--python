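"""Exception hierarchy shared across the package.

Exit-code contract of the command line interface: schema/config problems map
to exit code 2, unrealizable fixture requests to exit code 3.
"""


class AyrError(Exception):
    """Base class for all package errors."""


class SchemaError(AyrError):
    """The input file does not match the published cohort schema."""


class CohortReadError(AyrError):
    """A row failed to parse or violates a respondent invariant (strict mode)."""

    def __init__(self, message: str, row: int | None = None):
        self.row = row
        if row is not None:
            message = f"row {row}: {message}"
        super().__init__(message)


class InvariantError(AyrError):
    """A respondent record violates one of its structural invariants."""


class ConfigError(AyrError):
    """A cohort-generator configuration value is out of range."""


class UnrealizableFixtureError(AyrError):
    """The requested confusion matrix cannot be produced by the live rules."""


class EmptyMatrixError(AyrError):
    """Validity measures were requested for an all-zero confusion matrix."""
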