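"""Exception hierarchy.

All errors raised by the package derive from :class:`SheepRRError` so callers
can catch one type; subclasses distinguish bad files, bad parameters and
inputs that are structurally valid but carry no usable signal.
"""


class SheepRRError(Exception):
    """Base class for all package errors."""


class InputError(SheepRRError):
    """A required input file or directory is missing or unreadable."""


class FormatError(SheepRRError):
    """An input could be read but violates the expected dialect
    (e.g. inconsistent frame sizes, mask/frame dimension mismatch)."""


class ParameterError(SheepRRError, ValueError):
    """A configuration value is out of its valid range
    (e.g. band edge above Nyquist, CLAHE grid larger than the image)."""


class DegenerateInputError(SheepRRError, ValueError):
    """Structurally valid input that the operation cannot act on:
    empty pair list, all-zero mask, signal shorter than one window,
    no fully tracked trajectory."""


class ParseError(SheepRRError, ValueError):
    """A text token (e.g. an H:M:S duration) could not be parsed."""
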