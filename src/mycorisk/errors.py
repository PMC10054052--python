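"""Exception hierarchy for mycorisk.

All errors raised by the package derive from :class:`MycoriskError` so callers
can catch everything with one clause while still distinguishing input-format
problems from domain (value-range) problems.
"""


class MycoriskError(Exception):
    """Base class for all mycorisk errors."""


class FormatError(MycoriskError):
    """The input file does not have the required tabular structure."""


class ParseError(MycoriskError):
    """A cell could not be parsed; carries the 1-based data row number."""

    def __init__(self, message: str, row: int | None = None):
        super().__init__(message)
        self.row = row


class EmptyInputError(MycoriskError):
    """No usable records remain after validation."""


class DomainError(MycoriskError):
    """A value is outside the mathematical domain of an operation."""


class DegenerateSampleError(MycoriskError):
    """A statistical test received a sample with no usable variation."""


class ConfigError(MycoriskError):
    """A synthetic-data configuration is internally inconsistent."""
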