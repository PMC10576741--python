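"""Exception hierarchy.

Exit-code mapping used by the CLI: validation problems (bad config, bad
schema, bad arguments) exit 2; estimation failures exit 3.
"""


class GifluidError(Exception):
    """Base class for all package errors."""


class ValidationError(GifluidError, ValueError):
    """A configuration field, argument, or input value violates its contract."""


class SchemaError(ValidationError):
    """A tabular input does not conform to the expected record schema."""

    def __init__(self, message: str, row: int | None = None, column: str | None = None):
        loc = []
        if row is not None:
            loc.append(f"row {row}")
        if column is not None:
            loc.append(f"column {column!r}")
        if loc:
            message = f"{message} ({', '.join(loc)})"
        super().__init__(message)
        self.row = row
        self.column = column


class EstimationError(GifluidError, RuntimeError):
    """A fit did not converge or lacked usable data; carries diagnostics."""

    def __init__(self, message: str, diagnostics: dict | None = None):
        super().__init__(message)
        self.diagnostics = diagnostics or {}
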