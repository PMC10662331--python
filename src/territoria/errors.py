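"""Exception hierarchy.

User/configuration problems raise :class:`UserError`; problems with the data
itself (degenerate images, infeasible placements) raise :class:`DataError`.
The CLI maps these onto exit codes 1 and 2 respectively.
"""


class TerritoriaError(Exception):
    """Base class for all package errors."""


class UserError(TerritoriaError):
    """Invalid configuration, arguments, or file paths."""


class DataError(TerritoriaError):
    """The input data cannot support the requested computation."""


class ChannelMapError(UserError):
    """A channel map references a channel index absent from the file."""


class SchemaError(UserError):
    """A measurement table is missing required columns."""


class DegenerateHistogramError(DataError):
    """Thresholding attempted on a (near-)constant image."""


class PlacementError(DataError):
    """Territory placement infeasible after bounded rejection sampling."""


class ZeroSignalError(DataError):
    """A radial profile was requested where total signal is zero."""


class DegeneratePartitionError(DataError):
    """A ring partition left one or more rings empty (tiny mask)."""


class UndefinedAngleError(DataError):
    """An angle was requested for coincident centroids."""


class SchemeMismatchError(UserError):
    """Per-cell classification scheme does not match the measurement count."""
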