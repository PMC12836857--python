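"""Exception hierarchy for slicelogp.

All package-raised errors derive from :class:`SliceLogPError` so callers can
catch everything with one clause; the subclasses distinguish bad arguments,
unreadable data, and failures of the quantification itself (the CLI maps them
to distinct exit codes).
"""


class SliceLogPError(Exception):
    """Base class for all slicelogp errors."""


class DomainError(SliceLogPError, ValueError):
    """An argument is outside the physically meaningful domain."""


class ParseError(SliceLogPError):
    """A dataset could not be parsed.

    Parameters
    ----------
    message : str
    key : str, optional
        Name of the missing or malformed metadata key, when applicable.
    """

    def __init__(self, message: str, key: str | None = None):
        super().__init__(message)
        self.key = key


class QuantificationError(SliceLogPError):
    """log P could not be quantified from the processed spectra."""
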