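"""Exception hierarchy.

Every domain failure raises a subclass of :class:`DSDError` carrying a short
machine-readable ``error_class`` used by the CLI for exit diagnostics.
"""


class DSDError(Exception):
    """Base class for all domain errors."""

    error_class = "dsd-error"


class VolumeFormatError(DSDError):
    """Malformed or unreadable volume file."""

    error_class = "volume-format"


class DimensionalityError(DSDError):
    """An image does not have the required dimensionality."""

    error_class = "dimensionality"


class StreamlineFormatError(DSDError):
    """Unsupported or malformed tractogram file."""

    error_class = "streamline-format"


class ConfigurationError(DSDError):
    """Invalid or incomplete configuration (missing max_scale, bad params)."""

    error_class = "configuration"


class GridMismatchError(DSDError):
    """Volumes/maps do not share a common grid (shape + affine)."""

    error_class = "grid-mismatch"


class EmptyLesionError(DSDError):
    """Lesion mask contains no voxels."""

    error_class = "empty-lesion"


class NoTerritoryError(DSDError):
    """No informative morphospace territory survives thresholding."""

    error_class = "no-territory"


class DegenerateDataError(DSDError):
    """Input data carries no usable variance (constant scores, identical maps)."""

    error_class = "degenerate-data"
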