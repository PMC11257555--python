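"""Exception types shared across the toolkit."""


class PedcnsError(Exception):
    """Base class for all toolkit errors."""


class FormatError(PedcnsError):
    """A file does not conform to its expected tabular format."""


class RowError(PedcnsError):
    """A single row of an input file could not be interpreted."""

    def __init__(self, message: str, row: int | None = None):
        self.row = row
        if row is not None:
            message = f"row {row}: {message}"
        super().__init__(message)
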