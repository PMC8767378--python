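"""Exception hierarchy for the nasoform pipeline."""


class NasoformError(Exception):
    """Base class for all package errors."""


class ParameterError(NasoformError, ValueError):
    """An invalid configuration or generator parameter; names the field."""


class CalibrationError(NasoformError):
    """Ruler calibration failed (too few ticks, non-collinear, bad fit)."""


class MeasurementError(NasoformError):
    """A required landmark or calibration is missing for a measurement."""


class GeometryError(NasoformError):
    """Degenerate geometry (coincident points, missing profile point)."""


class ConfigurationError(NasoformError):
    """Inconsistent network or pipeline configuration."""


class DataError(NasoformError):
    """Empty or malformed dataset."""


class FeatureError(NasoformError):
    """A record is missing a feature the model was configured with."""


class StatError(NasoformError):
    """Degenerate sample for a statistical test (too small, zero variance)."""


class RenderError(NasoformError):
    """Synthetic scene cannot be rendered (e.g. does not fit in frame)."""


class ParseError(NasoformError):
    """A landmark/measurement file violates its schema; carries the JSON path."""

    def __init__(self, message: str, json_path: str = "$"):
        super().__init__(f"{json_path}: {message}")
        self.json_path = json_path
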