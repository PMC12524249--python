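"""Exception hierarchy shared across the toolkit."""


class DualViewError(Exception):
    """Base class for all toolkit errors."""


class InvalidArgumentError(DualViewError, ValueError):
    """An argument violates a documented precondition."""


class BehindCameraError(DualViewError):
    """A world point projects with non-positive depth (fails cheirality)."""


class DegenerateRayError(DualViewError):
    """A viewing ray is (numerically) parallel to the target plane."""


class DegenerateGeometryError(DualViewError):
    """A calibration problem is rank-deficient (too few or collinear points)."""


class UndefinedMetricError(DualViewError):
    """A metric is requested on an empty collection."""


class AlignmentError(DualViewError):
    """Prediction and ground-truth files share no frames."""


class ParseError(DualViewError):
    """A detection/correspondence file line could not be parsed."""

    def __init__(self, message: str, line_number: int | None = None):
        self.line_number = line_number
        if line_number is not None:
            message = f"line {line_number}: {message}"
        super().__init__(message)


class ConfigurationError(DualViewError):
    """An experiment configuration is missing or malformed."""


class StageError(DualViewError):
    """Wraps an error raised inside a named pipeline stage."""

    def __init__(self, stage: str, cause: BaseException):
        self.stage = stage
        self.cause = cause
        super().__init__(f"stage '{stage}' failed: {cause}")
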