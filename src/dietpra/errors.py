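"""Exception hierarchy for the exposure pipeline."""


class DietPraError(Exception):
    """Base class for all package errors."""


class SchemaError(DietPraError):
    """An input table is missing a required column."""

    def __init__(self, column: str, path: str | None = None):
        self.column = column
        self.path = path
        where = f" in {path}" if path else ""
        super().__init__(f"required column {column!r} missing{where}")


class ValidationError(DietPraError):
    """A row carries a value outside its allowed domain."""

    def __init__(self, message: str, row: int | None = None):
        self.row = row
        at = f" (row {row})" if row is not None else ""
        super().__init__(message + at)


class EmptyInputError(DietPraError):
    """An operation requiring at least one record received none."""


class DomainError(DietPraError, ValueError):
    """A scalar parameter is outside its mathematical domain."""


class InfeasibleTruncationError(DietPraError):
    """A truncation interval carries negligible probability mass."""


class DegenerateModelError(DietPraError):
    """Not enough detected values to fit a concentration model."""
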