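"""Exception hierarchy."""


class TorsionLabError(Exception):
    """Base class for all package errors."""


class ConfigurationError(TorsionLabError):
    """Invalid parameter values or inconsistent configuration."""


class InputError(TorsionLabError):
    """Malformed input data (wrong shape, empty image, ...)."""


class SegmentationError(TorsionLabError):
    """Iris segmentation produced no usable foreground.

    Carries the frame index so callers can skip and log the frame.
    """

    def __init__(self, message: str, frame_index: int | None = None):
        super().__init__(message)
        self.frame_index = frame_index


class TrainingError(TorsionLabError):
    """Training diverged (non-finite loss) or was misconfigured."""
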