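"""Exception hierarchy shared across the pipeline."""


class TomatoVisionError(Exception):
    """Base class for all package errors."""


class ParameterError(TomatoVisionError, ValueError):
    """A parameter violates an operation's precondition."""


class ShapeError(TomatoVisionError, ValueError):
    """Array dimensions are incompatible."""


class EmptyRegionError(TomatoVisionError, ValueError):
    """An operation that needs foreground pixels received an empty mask."""


class DataError(TomatoVisionError, ValueError):
    """Training data violate a fitting precondition (e.g. a single class)."""


class ModelStateError(TomatoVisionError, RuntimeError):
    """A prediction was requested from an untrained or mismatched model."""


class ImageIOError(TomatoVisionError, OSError):
    """An image file could not be read or written."""
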