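"""Exception hierarchy shared across the package."""


class TipsGeoError(Exception):
    """Base class for all package-specific errors."""


class DegeneratePathError(TipsGeoError):
    """All input points coincide, or a chord has zero length."""


class OutOfRangeError(TipsGeoError):
    """An arc-length position or chord extends beyond the path."""


class InsufficientLengthError(TipsGeoError):
    """An interval is too short for the requested chord/gap layout."""


class DegenerateVectorError(TipsGeoError):
    """A zero vector where a direction was required."""


class NoPathError(TipsGeoError):
    """The two seeds are not connected through non-background voxels."""


class BadSeedError(TipsGeoError):
    """A seed point falls in a background voxel."""


class InvalidLandmarksError(TipsGeoError):
    """Landmark arc positions violate their required ordering."""


class NoLumenError(TipsGeoError):
    """Every cross-section profile in the interval was empty."""


class NoEventsError(TipsGeoError):
    """Too few observed events to fit a hazards model."""


class ConvergenceError(TipsGeoError):
    """A model fit failed to converge (e.g. separation, collinearity)."""


class ParameterError(TipsGeoError):
    """An invalid parameter value (negative rate, bad spec, ...)."""
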