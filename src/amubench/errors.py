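"""Exception hierarchy shared across the package."""


class AmubenchError(Exception):
    """Base class for all package errors."""


class SchemaError(AmubenchError):
    """An input file does not follow the documented CSV schema."""


class ValidationError(AmubenchError):
    """Parsed input violates a data invariant (duplicates, non-positive values, ...)."""


class DomainError(AmubenchError):
    """An operation was called outside its domain (unknown category, too few farms, ...)."""


class JournalParseError(ValidationError):
    """One or more journal rows could not be parsed.

    Carries ``row_errors``: a list of ``(row_index, message)`` pairs, where
    ``row_index`` is the zero-based data-row position in the input file.
    """

    def __init__(self, row_errors):
        self.row_errors = list(row_errors)
        lines = "; ".join(f"row {i}: {msg}" for i, msg in self.row_errors[:10])
        more = "" if len(self.row_errors) <= 10 else f" (+{len(self.row_errors) - 10} more)"
        super().__init__(f"{len(self.row_errors)} malformed journal row(s): {lines}{more}")
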