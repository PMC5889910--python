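"""Exception hierarchy shared across the package."""


class BindspecError(Exception):
    """Base class for all package errors."""


class FormatError(BindspecError):
    """A file does not conform to the expected tabular layout."""


class ValidationError(BindspecError, ValueError):
    """An input value violates a physical or structural precondition."""


class InsufficientDataError(BindspecError):
    """Too few usable points remain for the requested fit."""


class RangeError(BindspecError):
    """A requested wavelength or window falls outside the measured grid."""
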