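"""Rigid-body kinematics and accuracy/precision statistics.

Covers the two evaluation quantities of a small-motion tracking study:
inter-marker distances (distance accuracy) and rigid-body displacement
between marker plates (translation and rotation accuracy), plus the
summary statistics used to report them:

* accuracy: mean and median of (measured - reference);
* precision: sample standard deviation (divisor n-1), or the pooled RMS
  deviation over repeated measurements

      eps = sqrt( 1/(l*m*n) * sum_k sum_i sum_j (d_kij - dbar_ki)^2 ),

  where ``dbar_ki`` is the per-position, per-distance mean over the n
  repeats.  The RMS uses the biased (divisor n) form exactly as written;
  it is algebraically the pooled biased SD over the l*m conditions.

Rotations are compared through the attitude vector ``a = n * alpha``
(axis-angle), orthogonally decomposed onto the object axes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.transform import Rotation
from scipy.stats import jarque_bera, kruskal, levene  # noqa: F401  (report parity)

from .camera import RigidTransform
from .errors import DegenerateFitError, MarkerLookupError, UndefinedPrecisionError

__all__ = [
    "AttitudeVector",
    "MeasurementReport",
    "inter_marker_distances",
    "grid_adjacency",
    "all_pairs",
    "rigid_body_transform",
    "attitude_decompose",
    "rms_precision",
    "summarize",
    "jarque_bera",
    "kruskal",
    "levene",
]


@dataclass(frozen=True)
class AttitudeVector:
    """Axis-angle representation of a rotation, decomposed on object axes.

    ``components`` are the signed projections of ``axis * angle`` onto
    the three object axes (degrees); their Euclidean norm equals
    ``|angle|`` when the axes are orthonormal.
    """

    axis: np.ndarray
    angle: float          # degrees
    components: np.ndarray  # degrees
    degenerate: bool = False  # angle ~ 0: axis is arbitrary


@dataclass(frozen=True)
class MeasurementReport:
    """Accuracy/precision summary of a set of measurement errors."""

    errors: np.ndarray
    kind: str
    accuracy_mean: float
    accuracy_median: float
    precision_sd: float   # sample SD (n-1); nan for a single error
    n: int

    def __str__(self):
        sd = "undefined" if np.isnan(self.precision_sd) else f"{self.precision_sd:.4f}"
        return (f"{self.kind}: {self.accuracy_mean:.4f} "
                f"({self.accuracy_median:.4f}) ± {sd}")


# ---------------------------------------------------------------------------
# distances

def inter_marker_distances(points, adjacency) -> np.ndarray:
    """Euclidean distances between referenced marker pairs, in mm.

    ``points`` maps marker id -> 3-vector (a dict, or anything with
    ``marker_id``/``position`` attributes in a list).
    """
    if not isinstance(points, dict):
        points = {p.marker_id: p.position for p in points}
    out = np.empty(len(adjacency))
    for k, (i, j) in enumerate(adjacency):
        try:
            a, b = points[i], points[j]
        except KeyError as exc:
            raise MarkerLookupError(f"marker id {exc.args[0]!r} missing") from exc
        out[k] = np.linalg.norm(np.asarray(a, float) - np.asarray(b, float))
    return out


def grid_adjacency(nrows: int = 8, ncols: int = 8):
    """4-neighbour adjacency of a grid labelled ``(row, col)``.

    An 8x8 grid yields the 112 horizontal/vertical neighbour pairs.
    """
    pairs = []
    for r in range(nrows):
        for c in range(ncols):
            if c + 1 < ncols:
                pairs.append(((r, c), (r, c + 1)))
            if r + 1 < nrows:
                pairs.append(((r, c), (r + 1, c)))
    return pairs


def all_pairs(ids):
    """All unordered id pairs (9 markers -> C(9,2) = 36)."""
    ids = list(ids)
    return [(ids[i], ids[j]) for i in range(len(ids))
            for j in range(i + 1, len(ids))]


# ---------------------------------------------------------------------------
# rigid motion between plates

def rigid_body_transform(ref_points, moved_points):
    """Least-squares rigid motion mapping ``ref`` onto ``moved``.

    Rotation from the cross-covariance SVD (Kabsch, with determinant
    sign correction), translation from the centroids.  Returns
    ``(RigidTransform, residual_rms_mm)``.

    Raises
    ------
    DegenerateFitError
        Fewer than 3 points or a collinear configuration.
    """
    ref = np.asarray(ref_points, dtype=float)
    mov = np.asarray(moved_points, dtype=float)
    if ref.shape != mov.shape or ref.ndim != 2 or ref.shape[0] < 3:
        raise DegenerateFitError("need >= 3 corresponding points")
    cr, cm = ref.mean(axis=0), mov.mean(axis=0)
    ref_c, mov_c = ref - cr, mov - cm
    if np.linalg.matrix_rank(ref_c, tol=1e-9 * max(1.0, np.abs(ref_c).max())) < 2:
        raise DegenerateFitError("collinear reference configuration")
    rot, rssd = Rotation.align_vectors(mov_c, ref_c)
    R = rot.as_matrix()
    t = cm - R @ cr
    residual = float(rssd / np.sqrt(len(ref)))
    return RigidTransform(R, t), residual


def attitude_decompose(transform, frame_axes=None) -> AttitudeVector:
    """Attitude vector ``n * alpha`` of a rotation, on given object axes.

    ``frame_axes`` is a 3x3 matrix whose *columns* are the object axes
    expressed in the frame of the rotation (identity by default).  The
    angle is ``arccos((trace R - 1)/2)`` in degrees; the axis comes from
    the skew-symmetric part, switching to the eigenvector branch near
    180 degrees where the skew part vanishes.
    """
    R = transform.rotation if isinstance(transform, RigidTransform) \
        else np.asarray(transform, dtype=float)
    axes = np.eye(3) if frame_axes is None else np.asarray(frame_axes, float)
    cos_a = np.clip((np.trace(R) - 1.0) / 2.0, -1.0, 1.0)
    angle = float(np.arccos(cos_a))
    if angle < 1e-12:
        return AttitudeVector(axis=np.array([0.0, 0.0, 1.0]), angle=0.0,
                              components=np.zeros(3), degenerate=True)
    if np.pi - angle > 1e-6:
        skew = np.array([R[2, 1] - R[1, 2], R[0, 2] - R[2, 0], R[1, 0] - R[0, 1]])
        axis = skew / (2.0 * np.sin(angle))
    else:
        # near 180 deg: unit eigenvector of R for eigenvalue +1
        w, V = np.linalg.eigh((R + R.T) / 2.0)
        axis = V[:, np.argmax(w)]
        # fix the (inherently ambiguous) sign from the largest skew entry
        skew = np.array([R[2, 1] - R[1, 2], R[0, 2] - R[2, 0], R[1, 0] - R[0, 1]])
        if np.linalg.norm(skew) > 1e-12 and skew @ axis < 0:
            axis = -axis
        elif np.linalg.norm(skew) <= 1e-12:
            k = int(np.argmax(np.abs(axis)))
            if axis[k] < 0:
                axis = -axis
    axis = axis / np.linalg.norm(axis)
    angle_deg = float(np.degrees(angle))
    components = angle_deg * (axis @ axes)
    return AttitudeVector(axis=axis, angle=angle_deg, components=components)


# ---------------------------------------------------------------------------
# statistics

def rms_precision(distance_sets) -> float:
    """Pooled RMS deviation over repeats of an ``l x m x n`` array.

    Axis order: positions (l) x distances (m) x repeats (n).  Requires
    n >= 2; deviations are taken from the per-(position, distance) mean
    over the repeats, with the biased 1/(l*m*n) divisor.
    """
    arr = np.asarray(distance_sets, dtype=float)
    if arr.ndim != 3:
        raise ValueError("expected an l x m x n array")
    if arr.shape[2] < 2:
        raise UndefinedPrecisionError("precision requires >= 2 repeats")
    dev = arr - arr.mean(axis=2, keepdims=True)
    return float(np.sqrt(np.mean(dev ** 2)))


def summarize(errors, kind: str = "distance") -> MeasurementReport:
    """Accuracy (mean, median) and precision (sample SD) of error values."""
    err = np.asarray(errors, dtype=float).ravel()
    if err.size == 0:
        raise ValueError("empty error set")
    sd = float(np.std(err, ddof=1)) if err.size > 1 else np.nan
    return MeasurementReport(
        errors=err, kind=kind,
        accuracy_mean=float(np.mean(err)),
        accuracy_median=float(np.median(err)),
        precision_sd=sd,
        n=int(err.size),
    )
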