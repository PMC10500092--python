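"""Exception hierarchy shared across the package.

Configuration problems (bad specs, unknown options, invariant violations in
user input) map to CLI exit code 2; anything else maps to exit code 1.
"""


class MTTreeError(Exception):
    """Base class for all package errors."""


class ConfigurationError(MTTreeError):
    """Invalid user-supplied configuration, spec, or hyperparameter value."""


class DataParseError(MTTreeError):
    """A value in an input table could not be parsed or violates an invariant.

    Carries the offending row index (0-based, data rows, header excluded)
    and column name when known.
    """

    def __init__(self, message: str, row: int | None = None, column: str | None = None):
        self.row = row
        self.column = column
        loc = []
        if column is not None:
            loc.append(f"column {column!r}")
        if row is not None:
            loc.append(f"row {row}")
        if loc:
            message = f"{message} ({', '.join(loc)})"
        super().__init__(message)


class SchemaError(MTTreeError):
    """Input data does not match the schema a model was trained on."""


class UnsupportedVersionError(MTTreeError):
    """Serialized model document has an unsupported schema version."""
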