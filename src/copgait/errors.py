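"""Exception hierarchy.

Two broad classes matter for the CLI exit-code contract: :class:`UsageError`
(bad arguments, wrong shapes — exit code 1) and :class:`DataError` (malformed
or degenerate input data — exit code 2).
"""


class CopgaitError(Exception):
    """Base class for all package errors."""


class UsageError(CopgaitError):
    """Caller error: invalid arguments, mismatched dimensions, unknown ids."""


class DataError(CopgaitError):
    """Problem with the data itself rather than how the call was made."""


class FormatError(DataError):
    """Malformed file content (bad matrix, inconsistent shapes, negatives)."""


class EmptyFrameError(DataError):
    """A pressure frame with zero total pressure where a COP is required."""


class EmptyTrajectoryError(DataError):
    """A recording with no frame carrying positive pressure."""


class DegenerateFootError(DataError):
    """Foot bounding box has zero extent along an axis; mapping undefined."""


class InsufficientDataError(DataError):
    """Fewer trajectory points than requested key points."""


class DegenerateFeatureError(DataError):
    """A feature column whose maximum is not strictly positive."""


class DegenerateClusterError(DataError):
    """A fuzzy cluster whose total membership mass vanished."""


class DegenerateFoldError(DataError):
    """A cross-validation fold whose training labels collapse to one class."""


class ConvergenceError(CopgaitError):
    """An iterative solver failed to reach its tolerance."""
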