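"""Exception types shared across the package."""


class SchemaError(ValueError):
    """An input table is missing required columns or is otherwise malformed."""


class RowParseError(ValueError):
    """One or more data rows could not be parsed.

    Carries ``(line_number, message)`` pairs in :attr:`row_errors`.
    """

    def __init__(self, row_errors):
        self.row_errors = list(row_errors)
        detail = "; ".join(f"line {ln}: {msg}" for ln, msg in self.row_errors)
        super().__init__(f"{len(self.row_errors)} malformed row(s): {detail}")


class FitError(RuntimeError):
    """A model fit failed (e.g. non-positive growth slope)."""
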