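"""Exception hierarchy for adashape.

Every error raised on purpose by the package derives from
:class:`AdaShapeError`, so callers can catch the whole family with one
``except`` clause while still distinguishing specific failure modes.
"""


class AdaShapeError(Exception):
    """Base class for all adashape errors."""


class InvalidDimensionError(AdaShapeError, ValueError):
    """A matrix or landmark count has the wrong shape (e.g. k < 3)."""


class InvalidInputError(AdaShapeError, ValueError):
    """Malformed arguments: empty ensembles, non-finite entries, bad p."""


class DegenerateConfigurationError(AdaShapeError, ValueError):
    """All landmarks coincide: centroid size is zero, no pre-shape exists."""


class OutOfDomainError(AdaShapeError, ValueError):
    """A tangent vector with norm > 1 cannot be exponentiated."""


class InvalidSubsampleError(AdaShapeError, ValueError):
    """Systematic landmark subsampling would leave fewer than 3 landmarks."""


class InvalidMeasurementError(AdaShapeError, ValueError):
    """Measurement table lacks FL or contains non-positive foot lengths."""


class DegenerateColumnError(AdaShapeError, ValueError):
    """A column with zero spread cannot be standardized."""


class UnsupportedDimensionError(AdaShapeError, ValueError):
    """2D landmark data (TPS 'LM=' blocks) or a non-3-part alpha matrix."""


class InvalidComparisonError(AdaShapeError, ValueError):
    """Recovery scoring requested between models of different order."""


class ArchiveVersionError(AdaShapeError, ValueError):
    """A model archive was written by an incompatible format version."""


class MalformedFileError(AdaShapeError, ValueError):
    """A landmark/measurement file could not be parsed; names the file."""
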