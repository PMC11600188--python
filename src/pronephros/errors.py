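"""Exception hierarchy shared across the package."""


class PronephrosError(Exception):
    """Base class for all package-specific errors."""


class GeometryError(PronephrosError):
    """A geometric precondition failed (out-of-bounds axis, empty ROI, ...)."""


class MissingChannelError(PronephrosError):
    """A required fluorescence channel could not be resolved."""


class FormatError(PronephrosError):
    """An input file could not be parsed as the expected format."""


class CalibrationError(PronephrosError):
    """Physical pixel/slice calibration is missing or invalid."""


class FitError(PronephrosError):
    """A regression or model fit could not be performed."""
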