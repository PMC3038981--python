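"""Exception hierarchy.

Every failure mode of the measurement pipeline raises a subclass of
:class:`CircstereoError` so callers can distinguish geometric degeneracies
(recoverable by re-imaging) from plain usage errors.
"""


class CircstereoError(Exception):
    """Base class for all package-specific errors."""


class DegenerateProjectionError(CircstereoError):
    """Point at or behind the projection centre cannot be projected."""


class NonEllipseError(CircstereoError):
    """Conic fitted to the edge points is not an ellipse."""


class InsufficientDataError(CircstereoError):
    """Too few (or collinear) points to fit a conic."""


class GeometryError(CircstereoError):
    """Impossible viewing geometry (e.g. ellipse subtending a hemisphere)."""


class FiducialNotFoundError(CircstereoError):
    """No branch combination of the four circles is coplanar within tolerance."""


class LabelingError(CircstereoError):
    """Vertex ordering of the fiducial quadrangle is ambiguous."""


class DegenerateViewError(CircstereoError):
    """Fiducial diagonals project to (nearly) parallel image lines."""


class DegenerateScaleError(CircstereoError):
    """Scaled-orthographic factor k is numerically zero."""


class InconsistentObservationError(CircstereoError):
    """Observation is not realizable by any rotation (|S/k| entries > 1)."""


class AmbiguousPoseError(CircstereoError):
    """Both pose candidates explain the observation equally well."""


class IllConditionedTriangulationError(CircstereoError):
    """Stereo rays are too close to parallel to intersect reliably."""


class AmbiguousMatchError(CircstereoError):
    """Two stereo marker pairings score within tolerance of each other."""


class MarkerLookupError(CircstereoError):
    """A referenced marker id is absent from the reconstruction."""


class DegenerateFitError(CircstereoError):
    """Rigid-body fit on a collinear or under-determined point set."""


class UndefinedPrecisionError(CircstereoError):
    """Precision requested from fewer than two repeats."""
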