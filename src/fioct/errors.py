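"""Exception hierarchy shared across the pipeline stages."""


class FioctError(Exception):
    """Base class for all fioct-specific errors."""


class InvalidParameterError(FioctError, ValueError):
    """A physical or configuration parameter is out of its valid range."""


class SurfaceNotFoundError(FioctError):
    """No column of the volume crosses the surface-detection threshold."""


class EmptyROIError(FioctError):
    """A region of interest contains no valid voxels/pixels."""


class DegenerateRangeError(FioctError, ValueError):
    """Normalization is undefined because all input values are equal."""


class PlacementError(FioctError):
    """Non-overlapping nucleus placement failed within the retry budget."""


class LeakageError(FioctError):
    """A sample or patient appears on both sides of a train/test split."""


class ConfigError(FioctError, ValueError):
    """A run configuration is malformed (unknown keys, missing paths)."""
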