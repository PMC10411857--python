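"""Named exceptions raised by the pipeline.

Every user-facing failure mode has a distinct class so callers (and the CLI)
can map them to exit codes without string matching.
"""


class PolarfishError(Exception):
    """Base class for all package errors."""


class InputError(PolarfishError):
    """Bad or missing input data (CLI exit code 2)."""


class InvariantError(PolarfishError):
    """A domain invariant was violated (CLI exit code 3)."""


# --- stack_io ---------------------------------------------------------------

class MissingFileError(InputError, FileNotFoundError):
    pass


class ChannelCountError(InputError):
    """TIFF does not contain the four required channels."""


class AmbiguousAxesError(InputError):
    """On-disk axis order cannot be determined and no override was given."""


class PolygonFormatError(InputError):
    """Unknown or unsupported outline file format."""


class TooFewVerticesError(InvariantError):
    """A polygon needs at least three vertices."""


class SelfIntersectingPolygonError(InvariantError):
    """The cell outline must be a simple (non self-crossing) polygon."""


# --- spot_detection ---------------------------------------------------------

class ConstantVolumeError(InvariantError):
    """Isodata threshold is undefined for a constant-intensity volume."""


class EmptyMaskError(InputError):
    """The detection mask selects no voxels."""


class TooFewVoxelsError(InputError):
    """Noise estimation needs a minimum number of masked voxels."""


class NotAnRnaChannelError(InputError):
    """Spot detection only runs on the rna1/rna2 channels."""


# --- cell_geometry ----------------------------------------------------------

class DuplicateAnchorError(InvariantError):
    """Two boundary clicks snapped to the same outline vertex."""


class AnchorOrderError(InvariantError):
    """Anchor clicks must proceed clockwise starting at the nuclear side."""


class DegenerateSegmentError(InvariantError):
    """A boundary segment has zero length."""


class PolygonOutsideImageError(InputError):
    """The drawn outline lies entirely outside the image frame."""


# --- polarity_stats ---------------------------------------------------------

class EmptyRecordsError(InputError):
    """An operation that needs at least one spot record received none."""


class DuplicateImageIdError(InputError):
    """Pooled tables require unique image identifiers."""


class InsufficientPairsError(InputError):
    """The matched-pairs test needs at least two usable (non-zero) pairs."""


class SchemaError(InputError):
    """A tabular input is missing required columns or has bad values."""
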