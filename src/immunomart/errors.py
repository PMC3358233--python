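"""Exception hierarchy shared by all immunomart modules."""


class ImmunomartError(Exception):
    """Base class for all package errors."""


class StoreError(ImmunomartError):
    """The store file is unusable (corrupt, wrong schema, unwritable path)."""


class ValidationError(ImmunomartError):
    """A record violates a type invariant; the message names the field."""

    def __init__(self, field: str, message: str):
        self.field = field
        super().__init__(f"{field}: {message}")


class DuplicateLoadError(ImmunomartError):
    """A batch file with the same (file_name, file_hash) was already loaded."""


class FormatError(ImmunomartError):
    """A sheet does not conform to the expected layout.

    Carries 1-based row/column coordinates when they are known.
    """

    def __init__(self, message: str, row: int | None = None, col: int | None = None):
        self.row = row
        self.col = col
        where = ""
        if row is not None or col is not None:
            where = f" (row={row}, col={col})"
        super().__init__(message + where)


class VocabularyError(ImmunomartError):
    """A value cannot be resolved against a controlled vocabulary."""


class LinkageError(ImmunomartError):
    """An identifier-mapping operation violated its contract."""


class QueryError(ImmunomartError):
    """A cube query references unknown levels, members or measures."""
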