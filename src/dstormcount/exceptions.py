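"""Exception hierarchy for the counting pipeline."""


class DstormCountError(Exception):
    """Base class for all package errors."""


class ConfigurationError(DstormCountError):
    """Unknown dialect, preset, or invalid parameter combination."""


class ParseError(DstormCountError):
    """A localization table could not be parsed (names the offending row)."""


class FormatError(DstormCountError):
    """A file is not in the expected on-disk format."""


class CalibrationError(DstormCountError):
    """No per-strand calibration factor can be produced."""


class DegenerateInputError(DstormCountError):
    """Input is degenerate for the requested operation (constant image,
    cluster with too few events, ...)."""
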