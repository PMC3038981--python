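"""Two-camera fusion: marker matching and ray-intersection reconstruction.

After each camera's pose relative to the fiducial plate is known, the
projection centres and the (eccentricity-corrected) marker centre rays
are transported into the fiducial frame.  Corresponding markers are
paired across the two views, the real circle branch is selected by the
agreement of the circle normals between views, and each 3D marker is
reconstructed as the midpoint of the common perpendicular of its two
rays; the residual ray-to-ray gap is reported as a quality measure.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from .camera import Ray
from .errors import AmbiguousMatchError, IllConditionedTriangulationError
from .fiducial import PoseSolution

__all__ = [
    "MarkerPoint3D",
    "to_fiducial_frame",
    "match_markers",
    "triangulate",
]

PARALLEL_TOL = 1e-6   # rad, minimum angle between stereo rays
MATCH_TOL = 4.0       # mm, maximum pairing cost for a valid match
AMBIG_TOL = 0.5       # mm, two pairings closer than this are ambiguous
TOL_NORMAL_STEREO = 0.2  # rad, branch selection by normal agreement


@dataclass(frozen=True)
class MarkerPoint3D:
    """A reconstructed marker in the fiducial frame.

    ``gap`` is the closest distance between the two camera rays; the
    position is the midpoint of the shortest connecting segment and is
    therefore equidistant from both rays.
    """

    position: np.ndarray
    gap: float
    marker_id: object = None
    per_camera_rays: tuple = ()

    def __post_init__(self):
        object.__setattr__(self, "position",
                           np.asarray(self.position, dtype=float))


def to_fiducial_frame(pose: PoseSolution, entity):
    """Transport a Ray or point from the camera into the fiducial frame.

    ``pose`` maps fiducial coordinates to camera coordinates, so entities
    observed in the camera frame are moved by the inverse transform.
    Rigid transport: lengths and angles are preserved exactly.
    """
    inv = pose.transform.inverse()
    if isinstance(entity, Ray):
        return inv.apply_ray(entity)
    return inv.apply(np.asarray(entity, dtype=float))


def triangulate(ray_l: Ray, ray_r: Ray,
                parallel_tol: float = PARALLEL_TOL) -> MarkerPoint3D:
    """Near-intersection of two rays: midpoint of the common perpendicular.

    Raises
    ------
    IllConditionedTriangulationError
        If the rays are within ``parallel_tol`` radians of parallel.
    """
    d1, d2 = ray_l.direction, ray_r.direction
    cross = np.cross(d1, d2)
    sin_angle = np.linalg.norm(cross)
    if sin_angle < parallel_tol:
        raise IllConditionedTriangulationError(
            f"rays nearly parallel (angle ~ {sin_angle:.3g} rad)")
    o1, o2 = ray_l.origin, ray_r.origin
    w = o2 - o1
    b = d1 @ d2
    # closest points: o1 + s d1, o2 + t d2
    s = (w @ d1 - b * (w @ d2)) / (1 - b * b)
    t = (b * (w @ d1) - w @ d2) / (1 - b * b)
    p1 = o1 + s * d1
    p2 = o2 + t * d2
    midpoint = (p1 + p2) / 2
    gap = float(np.linalg.norm(p1 - p2))
    return MarkerPoint3D(position=midpoint, gap=gap,
                         per_camera_rays=(ray_l, ray_r))


def _frame_rays(markers, pose):
    """Per-branch directions, normals and depth scales, fiducial frame.

    All centre rays of one camera emanate from its projection centre, so
    only the (n, 2, 3) direction arrays per branch plus the single
    origin are needed.  ``depth_scale`` is the distance from the camera
    centre to the interpreted circle centre per unit circle radius.
    """
    Rt = pose.transform.rotation.T
    origin = -Rt @ pose.transform.translation
    dirs = np.array([[Rt @ it.centre_ray.direction for it in pair]
                     for pair in markers])        # (n, 2, 3)
    normals = np.array([[Rt @ it.normal for it in pair]
                        for pair in markers])     # (n, 2, 3)
    depth = np.array([[np.linalg.norm(it.centre_unit_radius) for it in pair]
                      for pair in markers])       # (n, 2)
    return origin, dirs, normals, depth


def match_markers(left, right, pose_l: PoseSolution, pose_r: PoseSolution,
                  match_tol: float = MATCH_TOL,
                  ambig_tol: float = AMBIG_TOL,
                  tol_normal: float = TOL_NORMAL_STEREO):
    """Pair marker observations across the two views and reconstruct them.

    Parameters
    ----------
    left, right : sequences of (CircleInterpretation, CircleInterpretation)
        Both branch interpretations per detected marker, per camera.
    pose_l, pose_r : PoseSolution
        Fiducial-to-camera poses of the two views.

    The pairing cost couples the two views through the unknown physical
    circle radius: each interpretation places the 3D centre at
    ``O + r * depth_scale * direction`` for radius ``r``, and the cost of
    a candidate pair is the minimal distance between the two loci over a
    *common* r.  This subsumes the ray-ray gap and additionally rejects
    phantom pairings of rays that happen to lie in one epipolar plane
    (their implied circle radii disagree).  The real branch per marker is
    chosen as the branch pair whose circle normals agree between the
    views (falling back to the closest-normal pair when noise pushes all
    combinations outside ``tol_normal``).

    Pairing additionally enforces the stereo *ordering constraint*:
    admissible pairs are grouped into epipolar bands (connected
    components of the admissibility graph), and within each band markers
    are aligned monotonically in their angle from the baseline — the
    order of points along an epipolar line is the same in both views, so
    neighbour swaps inside a band (which the cost alone can barely
    distinguish under pixel noise) are excluded.  Markers visible in
    only one view are reported unmatched.

    Returns
    -------
    points : list of MarkerPoint3D
        ``marker_id`` is the pair ``(left_index, right_index)``.
    unmatched_left, unmatched_right : lists of int

    Raises
    ------
    AmbiguousMatchError
        If two markers of one view sit within ``ambig_tol`` of each
        other along the same epipolar line, so that no ordering can
        separate their pairings.
    """
    nl, nr = len(left), len(right)
    if nl == 0 or nr == 0:
        return [], list(range(nl)), list(range(nr))
    o_l, d_l, n_l, k_l = _frame_rays(left, pose_l)
    o_r, d_r, n_r, k_r = _frame_rays(right, pose_r)
    w = o_l - o_r
    mism = np.empty((2, 2, nl, nr))
    ang = np.empty((2, 2, nl, nr))
    for bl in range(2):
        for br in range(2):
            # common-radius centre mismatch: min_r |w + r (k_l d_l - k_r d_r)|
            v = (k_l[:, bl][:, None, None] * d_l[:, bl][:, None, :]
                 - k_r[:, br][None, :, None] * d_r[:, br][None, :, :])
            vv = np.einsum("ijk,ijk->ij", v, v)
            wv = v @ w
            with np.errstate(invalid="ignore", divide="ignore"):
                r_star = -wv / vv
            res = w[None, None, :] + r_star[..., None] * v
            m = np.linalg.norm(res, axis=-1)
            m[(r_star <= 0) | ~np.isfinite(r_star)] = np.inf
            mism[bl, br] = m
            dots = np.clip(n_l[:, bl] @ n_r[:, br].T, -1.0, 1.0)
            ang[bl, br] = np.arccos(dots)
    # branch selection per candidate pair: agreeing normals, then min cost
    agree = ang <= tol_normal
    mism_agree = np.where(agree, mism, np.inf)
    any_agree = agree.any(axis=(0, 1))
    flat_mism = mism_agree.reshape(4, nl, nr)
    flat_ang = ang.reshape(4, nl, nr)
    combo = np.where(any_agree, flat_mism.argmin(axis=0), flat_ang.argmin(axis=0))
    cost = np.take_along_axis(mism.reshape(4, nl, nr), combo[None], axis=0)[0]

    # Epipolar geometry (branch 0 directions; the two branches differ
    # only by the eccentricity shift, irrelevant here): every ray spans,
    # together with the baseline, one epipolar plane.  The plane angle
    # psi identifies the epipolar line a marker lies on; it is computed
    # from the ray directions only, so adjacent marker rows (separated
    # by ~mm-scale epipolar offsets) stay cleanly apart even under pixel
    # noise.
    baseline = o_r - o_l
    bnorm = np.linalg.norm(baseline)
    if bnorm < 1e-9:
        raise AmbiguousMatchError("coincident camera centres")
    bh = baseline / bnorm
    alpha_l = np.arccos(np.clip(d_l[:, 0] @ bh, -1.0, 1.0))
    alpha_r = np.arccos(np.clip(d_r[:, 0] @ bh, -1.0, 1.0))
    psi_l = _epipolar_angle(d_l[:, 0], bh)
    psi_r = _epipolar_angle(d_r[:, 0], bh)

    bands = _epipolar_bands(psi_l, psi_r)
    pairs = []
    depth = float(np.mean(k_l))  # nominal scene depth per unit radius (mm)
    for Ls, Rs in bands:
        Ls = sorted(Ls, key=lambda i: alpha_l[i])
        Rs = sorted(Rs, key=lambda j: alpha_r[j])
        # two markers indistinguishable along one epipolar line
        for seq, alpha in ((Ls, alpha_l), (Rs, alpha_r)):
            for a, b in zip(seq, seq[1:]):
                if depth * abs(alpha[b] - alpha[a]) < ambig_tol:
                    raise AmbiguousMatchError(
                        "two markers closer than the ambiguity tolerance "
                        "along one epipolar line")
        pairs.extend(_monotone_align(Ls, Rs, cost, match_tol))

    points = []
    matched_l, matched_r = set(), set()
    for i, j in pairs:
        bl, br = divmod(int(combo[i, j]), 2)
        ray_l = Ray(o_l, d_l[i, bl])
        ray_r = Ray(o_r, d_r[j, br])
        pt = triangulate(ray_l, ray_r)
        points.append(MarkerPoint3D(position=pt.position, gap=pt.gap,
                                    marker_id=(i, j),
                                    per_camera_rays=(ray_l, ray_r)))
        matched_l.add(i)
        matched_r.add(j)
    unmatched_left = [i for i in range(nl) if i not in matched_l]
    unmatched_right = [j for j in range(nr) if j not in matched_r]
    return points, unmatched_left, unmatched_right


#: rad, epipolar-plane angle separation below which two rays are taken to
#: lie on the same epipolar line (marker rows sit ~0.02 rad apart, the
#: angular noise of a detected centre is ~1e-5 rad)
BAND_TOL = 2e-3


def _epipolar_angle(dirs, bh):
    """Angle (mod pi) of the epipolar plane spanned by baseline and ray."""
    n = np.cross(np.broadcast_to(bh, dirs.shape), dirs)
    norm = np.linalg.norm(n, axis=-1, keepdims=True)
    norm[norm == 0] = 1.0
    n = n / norm
    t = np.array([0.0, 0.0, 1.0]) if abs(bh[2]) < 0.9 else np.array([0.0, 1.0, 0.0])
    u1 = np.cross(bh, t)
    u1 /= np.linalg.norm(u1)
    u2 = np.cross(bh, u1)
    return np.arctan2(n @ u2, n @ u1) % np.pi


def _epipolar_bands(psi_l, psi_r, band_tol: float = BAND_TOL):
    """Joint clustering of left/right rays into epipolar-line bands.

    Sorts all plane angles together and splits at gaps larger than
    ``band_tol`` (handling the mod-pi wrap by rotating the origin to the
    largest gap).  Returns a list of (left indices, right indices).
    """
    nl, nr = len(psi_l), len(psi_r)
    psi = np.concatenate([psi_l, psi_r])
    order = np.argsort(psi)
    gaps = np.diff(psi[order])
    wrap_gap = np.pi - (psi[order[-1]] - psi[order[0]])
    start = 0
    if wrap_gap < band_tol and len(order) > 1:
        # wrapped cluster: start the scan at the largest internal gap
        start = int(np.argmax(gaps)) + 1 if gaps.size else 0
        order = np.roll(order, -start)
        gaps = np.diff(np.unwrap(2 * psi[order]) / 2)
    bands = []
    current = [order[0]]
    for idx, g in zip(order[1:], gaps):
        if g > band_tol:
            bands.append(current)
            current = []
        current.append(idx)
    bands.append(current)
    out = []
    for members in bands:
        Ls = [int(m) for m in members if m < nl]
        Rs = [int(m) - nl for m in members if m >= nl]
        out.append((Ls, Rs))
    return out


def _monotone_align(Ls, Rs, cost, skip_penalty):
    """Order-preserving minimal-cost alignment of two marker sequences.

    Dynamic programming over the (sorted) band members; leaving a marker
    unmatched costs ``skip_penalty``, so a pairing is only made when it
    is cheaper than dropping both partners.
    """
    n, m = len(Ls), len(Rs)
    dp = np.zeros((n + 1, m + 1))
    dp[:, 0] = np.arange(n + 1) * skip_penalty
    dp[0, :] = np.arange(m + 1) * skip_penalty
    for a in range(1, n + 1):
        for b in range(1, m + 1):
            c = cost[Ls[a - 1], Rs[b - 1]]
            diag = c if c <= skip_penalty else np.inf
            dp[a, b] = min(dp[a - 1, b - 1] + diag,
                           dp[a - 1, b] + skip_penalty,
                           dp[a, b - 1] + skip_penalty)
    out = []
    a, b = n, m
    while a > 0 and b > 0:
        c = cost[Ls[a - 1], Rs[b - 1]]
        if c <= skip_penalty and np.isclose(dp[a, b], dp[a - 1, b - 1] + c):
            out.append((Ls[a - 1], Rs[b - 1]))
            a, b = a - 1, b - 1
        elif np.isclose(dp[a, b], dp[a - 1, b] + skip_penalty):
            a -= 1
        else:
            b -= 1
    return out
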