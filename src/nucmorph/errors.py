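"""Exception hierarchy.

Every failure mode raised by the library derives from :class:`NucmorphError`
so callers can catch pipeline errors without masking programming bugs.
"""


class NucmorphError(Exception):
    """Base class for all nucmorph errors."""


class UnitError(NucmorphError):
    """Physical-unit metadata missing or invalid (e.g. voxel size unknown)."""


class ShapeError(NucmorphError):
    """Array has the wrong dimensionality or incompatible shape."""


class FormatError(NucmorphError):
    """A file on disk does not conform to the expected tabular/image format."""


class SegmentationError(NucmorphError):
    """Segmentation produced an empty or degenerate mask."""


class PlacementError(NucmorphError):
    """Phantom object placement infeasible after bounded retries."""


class FitError(NucmorphError):
    """Nonlinear fit failed to converge after multi-start."""


class NormalizationError(NucmorphError):
    """Viability normalization impossible (missing or nonpositive controls)."""


class ConfigError(NucmorphError):
    """Study configuration invalid."""
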