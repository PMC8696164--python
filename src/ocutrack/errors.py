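"""Exception hierarchy shared across the tracking pipeline."""


class OcutrackError(Exception):
    """Base class for all ocutrack errors."""


class ConfigError(OcutrackError, ValueError):
    """Invalid or incomplete run configuration."""


class DegenerateFrameError(OcutrackError, ValueError):
    """Frame carries no usable intensity structure (e.g. constant image)."""


class SeedError(OcutrackError, ValueError):
    """Seed point is outside the frame interior or off the target blob."""


class InsufficientPointsError(OcutrackError, ValueError):
    """Too few contour points for the requested filter or fit."""


class FitError(OcutrackError, ValueError):
    """Shape fit failed (degenerate geometry or non-elliptical conic)."""


class InsufficientDataError(OcutrackError, ValueError):
    """Trace too short or too gappy for the requested analysis."""
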