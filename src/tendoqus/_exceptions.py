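"""Exception hierarchy.

Every error raised by the package derives from :class:`TendoQusError`
so callers (and the CLI) can catch the whole family at once.
"""


class TendoQusError(Exception):
    """Base class for all package errors."""


class ImageFormatError(TendoQusError):
    """The image file is not a single-channel 8-bit grayscale image."""


class MetadataError(TendoQusError):
    """The JSON sidecar is missing or carries invalid metadata."""


class TableSchemaError(TendoQusError):
    """A subject CSV is missing mandatory columns."""


class TableParseError(TendoQusError):
    """A subject CSV row holds an unparseable value; names the row."""


class GeometryError(TendoQusError):
    """An ROI is empty or extends beyond the image bounds."""


class LabelingError(TendoQusError):
    """Reference criteria cannot be evaluated (missing sex/measurements)."""


class CalibrationError(TendoQusError):
    """ROC/AUC machinery was handed a degenerate input (one class only)."""


class FitError(TendoQusError):
    """A model fit is impossible (e.g. constant predictor)."""


class StatsError(TendoQusError):
    """A group-comparison test was handed degenerate group sizes."""


class ParameterError(TendoQusError):
    """Invalid simulation parameters."""


class InfeasibleMixtureError(ParameterError):
    """The requested ROI moments cannot be met by the texture mixture."""
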