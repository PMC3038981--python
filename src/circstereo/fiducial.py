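"""Camera pose estimation from a four-coplanar-circle fiducial marker.

The fiducial is a planar plate carrying four black circles whose centres
form an asymmetric convex quadrangle; the coordinate origin of the
fiducial frame is the cross point of the quadrangle's diagonals.  Pose
estimation proceeds in four steps:

1. **label_fiducial** — among the two circle interpretations per ellipse,
   select the branch combination whose four circle planes are mutually
   coplanar (the real circles are coplanar, the imaginary ones are not),
   and order the four circles to the model vertices by the asymmetric
   distance-to-cross-point signature.
2. **perspective_to_orthogonal** — convert the perspective projections
   ``r_i = E + t_i e_i`` of the circle centres into orthographic
   projections ``p_i = E + h_i e_i`` on the same rays, using the
   assumption that the image plane passes through the diagonal cross
   point and that the cross point divides the diagonals at the known
   model ratios.
3. **solve_scaled_orthographic** — solve the 8x4 linear system
   ``A s = q`` in the least-squares sense, reshape ``s`` into the 2x2
   matrix ``S``; the scale is ``k = max(svd(S))``, the upper-left 2x2
   block of the rotation is ``S/k``, and the remaining entries follow
   from the unit-norm rows/columns and ``det R = +1``, leaving exactly
   two right-handed completions.
4. **resolve_ambiguity** — keep the completion whose perspectively
   reprojected circle centres converge to the projection centre ``O``,
   i.e. the one with the smaller reprojection residual.

The depth component of the translation is closed through the scale:
``z_t = d / k`` (mm), which is exact under the cross-point assumption.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass

import numpy as np
import yaml

from .camera import CameraIntrinsics, RigidTransform
from .circle import CircleInterpretation, interpret_circle
from .errors import (
    AmbiguousPoseError,
    DegenerateScaleError,
    DegenerateViewError,
    FiducialNotFoundError,
    InconsistentObservationError,
    LabelingError,
)

__all__ = [
    "FiducialModel",
    "FiducialObservation",
    "PoseSolution",
    "default_fiducial",
    "label_fiducial",
    "perspective_to_orthogonal",
    "solve_scaled_orthographic",
    "resolve_ambiguity",
    "estimate_pose",
    "load_fiducial",
    "save_fiducial",
]

log = logging.getLogger(__name__)

TOL_NORMAL = 1e-3       # rad, coplanarity of circle normals (noise-free default)
TOL_PLANE_REL = 0.01    # plane-offset spread relative to the quadrangle diagonal
TIE_TOL = 1e-9          # mm, reprojection-residual tie


def _line_intersection(p1, p2, p3, p4):
    """Intersection of lines (p1,p2) and (p3,p4) in 2D."""
    d1, d2 = p2 - p1, p4 - p3
    M = np.column_stack([d1, -d2])
    det = np.linalg.det(M)
    if abs(det) < 1e-12 * max(np.linalg.norm(d1) * np.linalg.norm(d2), 1e-30):
        raise DegenerateViewError("diagonals are (nearly) parallel")
    st = np.linalg.solve(M, p3 - p1)
    return p1 + st[0] * d1


@dataclass(frozen=True)
class FiducialModel:
    """Planar geometry of the four-circle fiducial plate.

    ``circle_centres`` are the four vertices (mm) in the fiducial plane,
    with the origin at the cross point of the diagonals (1-3 and 2-4).
    The quadrangle must be convex and asymmetric: the four vertex-to-
    cross-point distances must be pairwise distinct by at least 5% so
    that vertex labelling is unambiguous under any ordering.
    """

    circle_centres: np.ndarray
    circle_diameter: float = 5.0

    def __post_init__(self):
        V = np.asarray(self.circle_centres, dtype=float)
        if V.shape != (4, 2):
            raise ValueError("need four planar circle centres")
        object.__setattr__(self, "circle_centres", V)
        cross = _line_intersection(V[0], V[2], V[1], V[3])
        if np.linalg.norm(cross) > 1e-9:
            raise ValueError("origin must be the diagonal cross point "
                             "(use FiducialModel.from_vertices)")
        # convexity: cross point strictly inside both diagonals
        for i, j in ((0, 2), (1, 3)):
            if np.dot(-V[i], V[j] - V[i]) <= 0 or np.dot(-V[j], V[i] - V[j]) <= 0:
                raise ValueError("quadrangle is not convex")
        dists = np.sort(np.linalg.norm(V, axis=1))
        if np.any(np.diff(dists) / dists[:-1] < 0.05):
            raise ValueError("vertex-to-cross-point distances must be "
                             "pairwise distinct by >= 5%")
        if self.circle_diameter <= 0:
            raise ValueError("circle_diameter must be positive")

    @classmethod
    def from_vertices(cls, vertices, circle_diameter: float = 5.0) -> "FiducialModel":
        """Build a model from arbitrary convex vertices, recentring the
        coordinates on the diagonal cross point."""
        V = np.asarray(vertices, dtype=float)
        cross = _line_intersection(V[0], V[2], V[1], V[3])
        return cls(V - cross, circle_diameter)

    @property
    def diagonal_ratios(self) -> np.ndarray:
        """Fractions at which the cross point divides diagonals 1-3 and 2-4."""
        L = np.linalg.norm(self.circle_centres, axis=1)
        return np.array([L[0] / (L[0] + L[2]), L[1] / (L[1] + L[3])])

    @property
    def diagonal_length(self) -> float:
        V = self.circle_centres
        return float(max(np.linalg.norm(V[2] - V[0]), np.linalg.norm(V[3] - V[1])))

    @property
    def signature(self) -> np.ndarray:
        """Vertex-to-cross-point distances normalized to unit sum."""
        L = np.linalg.norm(self.circle_centres, axis=1)
        return L / L.sum()

    def points3(self) -> np.ndarray:
        """Vertices as 3D points in the fiducial frame (z = 0)."""
        return np.column_stack([self.circle_centres, np.zeros(4)])


def default_fiducial(circle_diameter: float = 5.0) -> FiducialModel:
    """The bundled asymmetric fiducial quadrangle (~20 mm across)."""
    vertices = np.array([[-11.0, -7.0], [13.0, -9.0], [9.0, 11.0], [-8.0, 14.0]])
    return FiducialModel.from_vertices(vertices, circle_diameter)


@dataclass(frozen=True)
class FiducialObservation:
    """Perspective and recovered orthographic projections of the quadrangle.

    All image quantities are metric (mm on the image plane, origin at the
    principal point).  ``p[i] = h[i] * e[i]`` lies on the ray from the
    principal point through ``r[i] = t[i] * e[i]``.
    """

    r: np.ndarray          # (4, 2) perspective projections (ecc-corrected)
    p: np.ndarray          # (4, 2) orthographic projections
    t_lengths: np.ndarray  # (4,)
    h_lengths: np.ndarray  # (4,)
    cross_point: np.ndarray  # (2,) image of the diagonal cross point


@dataclass(frozen=True)
class PoseSolution:
    """Candidate or chosen fiducial-to-camera pose."""

    transform: RigidTransform
    scale: float
    residual: float = np.nan  # mm, reprojection RMS of the 4 centres
    chosen: bool = False

    def __post_init__(self):
        if self.scale <= 0:
            raise ValueError("scale must be positive")


# ---------------------------------------------------------------------------

def _coplanarity_score(interps):
    """(max pairwise normal angle, plane-offset spread / quadrangle extent).

    Computed on the unit-radius 3D centres, so the score is independent
    of the (unknown at this stage) physical circle radius.
    """
    normals = np.array([it.normal for it in interps])
    centres = np.array([it.centre_unit_radius for it in interps])
    max_ang = 0.0
    for i, j in itertools.combinations(range(4), 2):
        c = np.clip(normals[i] @ normals[j], -1.0, 1.0)
        max_ang = max(max_ang, float(np.arccos(c)))
    n_mean = normals.mean(axis=0)
    n_mean /= np.linalg.norm(n_mean)
    offsets = centres @ n_mean
    extent = max(float(np.linalg.norm(centres[i] - centres[j]))
                 for i, j in itertools.combinations(range(4), 2))
    rel_spread = float(offsets.max() - offsets.min()) / max(extent, 1e-30)
    return max_ang, rel_spread


def label_fiducial(candidates, model: FiducialModel,
                   intrinsics: CameraIntrinsics,
                   tol_normal: float = TOL_NORMAL,
                   tol_plane_rel: float = TOL_PLANE_REL):
    """Select the coplanar branch combination and order the four circles.

    Parameters
    ----------
    candidates : sequence of 4 pairs of CircleInterpretation
        Output of :func:`circstereo.circle.interpret_circle` for the four
        fiducial ellipses (any order).
    model : FiducialModel
    tol_normal : float, radians
        Maximum pairwise angle between the four circle normals.
    tol_plane_rel : float
        Maximum spread of plane offsets, relative to the mean offset
        scaled by the quadrangle diagonal (depth-scale free).

    Returns
    -------
    r_centres : (4, 2) array
        Eccentricity-corrected perspective centres, metric image
        coordinates, ordered to match the model vertices.
    branches : tuple of 4 ints
        Selected branch (0 or 1) per input ellipse, in the returned order.

    Raises
    ------
    FiducialNotFoundError
        No branch combination is coplanar within tolerance.
    LabelingError
        The distance signature does not single out one vertex ordering.
    """
    if len(candidates) != 4:
        raise FiducialNotFoundError(
            f"need exactly four fiducial circles, got {len(candidates)}")
    best = None
    best_score = np.inf
    for branches in itertools.product((0, 1), repeat=4):
        interps = [candidates[i][b] for i, b in enumerate(branches)]
        ang, rel_spread = _coplanarity_score(interps)
        if ang <= tol_normal and rel_spread <= tol_plane_rel:
            score = ang + rel_spread
            if score < best_score:
                best_score = score
                best = (branches, interps)
    if best is None:
        raise FiducialNotFoundError(
            "no branch combination of the four circles is coplanar "
            f"within tol_normal={tol_normal} rad")
    branches, interps = best

    order = _order_vertices(interps, model)
    interps = [interps[i] for i in order]
    branches = tuple(branches[i] for i in order)
    d = intrinsics.d_mm
    r = np.array([d * it.centre_unit_radius[:2] / it.centre_unit_radius[2]
                  for it in interps])
    return r, branches, order


def _order_vertices(interps, model: FiducialModel):
    """Match the four coplanar circles to the model vertices.

    Works on the (scale-free) 3D centres: computes the in-plane diagonal
    cross point and compares the normalized distance signature with the
    model's, over the 8 cyclic orderings of the convex hull.
    """
    centres = np.array([it.centre_unit_radius for it in interps])
    n = np.array([it.normal for it in interps]).mean(axis=0)
    n /= np.linalg.norm(n)
    origin = centres.mean(axis=0)
    u = centres[0] - origin
    u -= (u @ n) * n
    u /= np.linalg.norm(u)
    v = np.cross(n, u)
    P = np.column_stack([(centres - origin) @ u, (centres - origin) @ v])
    hull = _convex_hull_order(P)
    sig_model = model.signature
    best, second = None, np.inf
    best_err = np.inf
    for rot in range(4):
        for flip in (False, True):
            idx = np.roll(hull[::-1] if flip else hull, rot)
            try:
                cross = _line_intersection(P[idx[0]], P[idx[2]], P[idx[1]], P[idx[3]])
            except DegenerateViewError:
                continue
            L = np.linalg.norm(P[idx] - cross, axis=1)
            sig = L / L.sum()
            err = float(np.abs(sig - sig_model).max())
            if err < best_err:
                second = best_err
                best_err, best = err, idx
            elif err < second:
                second = err
    if best is None:
        raise LabelingError("no convex ordering found")
    if second < 2 * best_err + 0.005:
        raise LabelingError(
            f"ambiguous vertex ordering (signature errors {best_err:.4g} "
            f"vs {second:.4g})")
    return list(best)


def _convex_hull_order(P: np.ndarray):
    """Counter-clockwise ordering of 4 convex planar points."""
    c = P.mean(axis=0)
    ang = np.arctan2(P[:, 1] - c[1], P[:, 0] - c[0])
    return np.argsort(ang)


def perspective_to_orthogonal(r: np.ndarray, model: FiducialModel,
                              intrinsics: CameraIntrinsics) -> FiducialObservation:
    """Convert perspective centre projections to orthographic ones.

    ``r`` holds the four corrected perspective centres in metric image
    coordinates (origin at the principal point), ordered to match the
    model.  The orthographic points ``p_i = h_i e_i`` are fixed by two
    constraints inherited from the model: both segments ``p1 p3`` and
    ``p2 p4`` pass through the image of the diagonal cross point, and the
    cross point divides them at the model's diagonal ratios.  Under the
    assumption that the image plane passes through the 3D cross point,
    this linear system has a unique solution which *is* the orthographic
    projection of the (depth-normalized) quadrangle — no further scale
    normalization is required or applied.
    """
    r = np.asarray(r, dtype=float)
    cross = _line_intersection(r[0], r[2], r[1], r[3])
    t = np.linalg.norm(r, axis=1)
    if np.any(t < 1e-12):
        raise DegenerateViewError("a circle centre projects onto the principal point")
    e = r / t[:, None]
    rho = model.diagonal_ratios
    h = np.zeros(4)
    for (i, j, rho_ij) in ((0, 2, rho[0]), (1, 3, rho[1])):
        M = np.column_stack([(1 - rho_ij) * e[i], rho_ij * e[j]])
        det = np.linalg.det(M)
        if abs(det) < 1e-12:
            raise DegenerateViewError("degenerate ray geometry for a diagonal")
        sol = np.linalg.solve(M, cross)
        h[i], h[j] = sol
    p = e * h[:, None]
    return FiducialObservation(r=r, p=p, t_lengths=t, h_lengths=h, cross_point=cross)


def solve_scaled_orthographic(obs: FiducialObservation, model: FiducialModel,
                              intrinsics: CameraIntrinsics,
                              cond_warn: float = 1e8) -> tuple:
    """Scaled-orthographic pose fit; returns the two candidate solutions.

    Solves the 8x4 least-squares system built from the model coordinates
    and the orthographic projections (relative to the image cross point),
    reshapes the solution into the 2x2 matrix ``S``, takes the scale as
    the largest singular value of ``S`` and completes the two feasible
    rotations.  The translation is ``(x_t, y_t, d) / k`` in mm, which
    places the fiducial origin at the 3D diagonal cross point.
    """
    X0 = model.circle_centres
    A = np.zeros((8, 4))
    q = np.zeros(8)
    for i in range(4):
        A[2 * i, 0:2] = X0[i]
        A[2 * i + 1, 2:4] = X0[i]
        q[2 * i] = obs.p[i, 0] - obs.cross_point[0]
        q[2 * i + 1] = obs.p[i, 1] - obs.cross_point[1]
    cond = np.linalg.cond(A)
    if cond > cond_warn:
        warnings.warn(f"fiducial system poorly conditioned (cond={cond:.3g})",
                      stacklevel=2)
    s, *_ = np.linalg.lstsq(A, q, rcond=None)
    S = s.reshape(2, 2)
    k = float(np.linalg.svd(S, compute_uv=False).max())
    if k < 1e-12:
        raise DegenerateScaleError("scaled-orthographic factor k is zero")
    B = S / k
    tol = 1e-6
    if np.any(np.abs(B) > 1 + tol):
        raise InconsistentObservationError(
            "observation not realizable by any rotation (|S/k| > 1)")
    m13sq = 1.0 - B[0, 0] ** 2 - B[0, 1] ** 2
    m23sq = 1.0 - B[1, 0] ** 2 - B[1, 1] ** 2
    m13 = np.sqrt(max(0.0, m13sq))
    m23 = np.sqrt(max(0.0, m23sq))
    v = -(B[0, 0] * B[1, 0] + B[0, 1] * B[1, 1])  # required r13 * r23
    sgn = np.sign(v) if abs(v) > 1e-12 else 1.0
    d = intrinsics.d_mm
    t3 = np.array([obs.cross_point[0], obs.cross_point[1], d]) / k
    sols = []
    for s13 in (+1.0, -1.0):
        row1 = np.array([B[0, 0], B[0, 1], s13 * m13])
        row2 = np.array([B[1, 0], B[1, 1], s13 * sgn * m23])
        row3 = np.cross(row1, row2)
        R = np.vstack([row1, row2, row3])
        sols.append(PoseSolution(transform=RigidTransform(R, t3), scale=k))
    return tuple(sols)


def resolve_ambiguity(cands, r: np.ndarray, model: FiducialModel,
                      intrinsics: CameraIntrinsics,
                      tie_tol: float = TIE_TOL) -> PoseSolution:
    """Choose the pose whose reprojected centres converge to ``O``.

    Each candidate's four reconstructed 3D centres are projected
    perspectively and scored against the corrected centres ``r``; the
    candidate with the smaller RMS residual wins.

    Raises
    ------
    AmbiguousPoseError
        If the two residuals differ by less than ``tie_tol`` (mm) while
        the poses differ materially; the caller may break the tie with
        the second camera.
    """
    d = intrinsics.d_mm
    X0 = model.points3()
    scored = []
    for cand in cands:
        P = cand.transform.apply(X0)
        proj = d * P[:, :2] / P[:, 2:3]
        res = float(np.sqrt(np.mean((proj - r) ** 2)))
        scored.append(PoseSolution(transform=cand.transform, scale=cand.scale,
                                   residual=res))
    scored.sort(key=lambda ps: ps.residual)
    if abs(scored[0].residual - scored[1].residual) < tie_tol:
        raise AmbiguousPoseError(
            f"pose candidates tie at residual {scored[0].residual:.3g} mm "
            "(fronto-parallel/orthographic degeneracy; a second view can "
            "break the tie)")
    win = scored[0]
    return PoseSolution(transform=win.transform, scale=win.scale,
                        residual=win.residual, chosen=True)


def estimate_pose(ellipses, model: FiducialModel, intrinsics: CameraIntrinsics,
                  tol_normal: float = TOL_NORMAL,
                  tol_plane_rel: float = TOL_PLANE_REL) -> PoseSolution:
    """Full pose pipeline from the four fiducial image ellipses."""
    candidates = [interpret_circle(e, intrinsics) for e in ellipses]
    r, _, _ = label_fiducial(candidates, model, intrinsics,
                             tol_normal=tol_normal, tol_plane_rel=tol_plane_rel)
    obs = perspective_to_orthogonal(r, model, intrinsics)
    cands = solve_scaled_orthographic(obs, model, intrinsics)
    return resolve_ambiguity(cands, r, model, intrinsics)


# ---------------------------------------------------------------------------
# model file I/O

def load_fiducial(path) -> FiducialModel:
    """Load a fiducial model YAML; coordinates are recentred and checked."""
    with open(path) as fh:
        data = yaml.safe_load(fh)
    return FiducialModel.from_vertices(
        np.asarray(data["circle_centres"], dtype=float),
        float(data.get("circle_diameter", 5.0)),
    )


def save_fiducial(model: FiducialModel, path) -> None:
    data = {
        "circle_centres": [[float(x) for x in v] for v in model.circle_centres],
        "circle_diameter": float(model.circle_diameter),
    }
    with open(path, "w") as fh:
        yaml.safe_dump(data, fh)
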