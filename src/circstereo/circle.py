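"""Eccentricity-corrected circle-centre determination from one image ellipse.

The perspective image of a flat circle is an ellipse, but the centre of
that ellipse is *not* the image of the circle's centre unless the circle
is parallel to the image plane — the discrepancy is the *eccentricity* of
the projected circle.  This module recovers, from a single fitted ellipse
and the camera intrinsics, the two 3D circle interpretations that are
exactly consistent with the observation:

* the **real** circle (the physical marker), and
* the **imaginary** circle (the mirror solution on the other side of the
  viewing cone),

each as a centre ray through the projection centre ``O`` plus the unit
normal of the circle plane.  Which branch is real cannot be decided from
one view alone; the four-circle coplanarity test (fiducial) or the
agreement of normals between two cameras (stereo) disambiguates.

Construction
------------
The ellipse and ``O`` span an oblique cone.  Rotating the cone so that
its bisecting line coincides with the image ``Z``-axis brings it to the
principal-axis form ``l1 x^2 + l2 y^2 + l3 z^2 = 0`` with
``l1 >= l2 > 0 > l3``; the rotated cone meets the image plane in an
axis-aligned ellipse centred at the principal point.  The circle planes
then make the tilt angle ``gamma`` with the image plane where

    sin(gamma) = +/- sqrt((1 - a^2/b^2) / (1 + a^2/d^2)),

``a <= b`` being the semi-axes of the aligned ellipse and ``d`` the
principal distance, both in mm.  Rotating the circle plane by ``+gamma``
and ``-gamma`` and transporting the resulting centre rays back through
the transposed alignment rotation yields the two interpretations.  All
cone algebra is carried out in the metric camera frame.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .camera import CameraIntrinsics, Ray
from .detect import ImageEllipse
from .errors import GeometryError

__all__ = [
    "CircleInterpretation",
    "AlignedCone",
    "ellipse_to_metric_conic",
    "align_cone",
    "gamma_from_ellipse",
    "interpret_circle",
]

_EIG_TOL = 1e-12


@dataclass(frozen=True)
class CircleInterpretation:
    """One 3D circle consistent with an observed image ellipse.

    Attributes
    ----------
    centre_ray : Ray
        Ray from ``O`` through the (eccentricity-corrected) projected
        circle centre, camera frame.
    normal : (3,) unit vector
        Circle-plane normal, camera frame, oriented towards the camera
        (``normal . centre_ray.direction < 0``).
    label : str
        ``"real"`` or ``"imaginary"``; provisional when produced from a
        single view (ordered by increasing centre shift), firm only after
        the coplanarity or stereo tests.
    gamma : float, radians
        Tilt of the circle plane against the image plane after cone
        alignment, in ``[0, pi/2)``.
    centre_unit_radius : (3,) vector, mm
        The 3D circle centre under the assumption of unit circle radius;
        scales linearly with the physical radius.
    centre_shift_px : float
        Image distance between the raw ellipse centre and the corrected
        projected centre (the eccentricity, in pixels).
    """

    centre_ray: Ray
    normal: np.ndarray
    label: str
    gamma: float
    centre_unit_radius: np.ndarray
    centre_shift_px: float

    def centre_at_radius(self, radius: float) -> np.ndarray:
        """3D centre of the interpreted circle for a known physical radius."""
        return self.centre_unit_radius * radius


@dataclass(frozen=True)
class AlignedCone:
    """The viewing cone rotated so its bisecting line is the image Z-axis.

    ``rotation_to_axis`` maps camera-frame vectors into the aligned
    (principal-axis) frame; its transpose maps back.  ``aligned_ellipse``
    is the intersection of the rotated cone with the image plane: an
    axis-aligned ellipse centred at the principal point with
    ``semi_minor`` along the aligned x-axis.
    """

    rotation_to_axis: np.ndarray
    semi_minor: float
    semi_major: float
    eigenvalues: np.ndarray  # (l1 >= l2 > 0 > l3)


def ellipse_to_metric_conic(e: ImageEllipse, intrinsics: CameraIntrinsics) -> np.ndarray:
    """Homogeneous conic matrix of an image ellipse in metric plane coords.

    Coordinates are mm on the image plane, origin at the principal point.
    """
    c = intrinsics.pixel_to_metric(e.centre)
    a = e.semi_minor * intrinsics.pixel_pitch
    b = e.semi_major * intrinsics.pixel_pitch
    u = np.array([np.cos(e.orientation), np.sin(e.orientation)])  # major axis
    v = np.array([-u[1], u[0]])
    A2 = np.outer(u, u) / b ** 2 + np.outer(v, v) / a ** 2
    g = -A2 @ c
    A = np.zeros((3, 3))
    A[:2, :2] = A2
    A[:2, 2] = g
    A[2, :2] = g
    A[2, 2] = c @ A2 @ c - 1
    return A


def _cone_quadric(e: ImageEllipse, intrinsics: CameraIntrinsics) -> np.ndarray:
    """Quadric of the viewing cone through O with base ellipse ``e``."""
    A = ellipse_to_metric_conic(e, intrinsics)
    d = intrinsics.d_mm
    D = np.diag([d, d, 1.0])
    Q = D @ A @ D
    return (Q + Q.T) / 2


def align_cone(e: ImageEllipse, intrinsics: CameraIntrinsics) -> AlignedCone:
    """Rotate the viewing cone into its principal-axis (bisected) form.

    Raises
    ------
    GeometryError
        If the conic does not bound a proper cone (ellipse subtending a
        hemisphere or worse — impossible for a physical marker).
    """
    Q = _cone_quadric(e, intrinsics)
    w, V = np.linalg.eigh(Q)
    if np.sum(w > 0) == 1:  # normalize sign: two positive, one negative
        w, V = -w, V
    order = np.argsort(w)[::-1]  # l1 >= l2 > 0 > l3
    w = w[order]
    V = V[:, order]
    if not (w[0] >= w[1] > 0 > w[2]):
        raise GeometryError("image conic does not define a viewing cone")
    e3 = V[:, 2]
    if e3[2] < 0:  # cone axis towards the scene
        e3 = -e3
    e1 = V[:, 0]
    e2 = np.cross(e3, e1)
    R_cam_from_axis = np.column_stack([e1, e2, e3])
    d = intrinsics.d_mm
    semi_minor = d * np.sqrt(-w[2] / w[0])
    semi_major = d * np.sqrt(-w[2] / w[1])
    return AlignedCone(
        rotation_to_axis=R_cam_from_axis.T,
        semi_minor=float(semi_minor),
        semi_major=float(semi_major),
        eigenvalues=w,
    )


def gamma_from_ellipse(a: float, b: float, d: float) -> tuple[float, float]:
    """Tilt ``+/- gamma`` of the circle plane for the axis-aligned cone.

    Parameters are the semi-minor axis ``a``, semi-major axis ``b`` of the
    aligned ellipse and the principal distance ``d``, all in mm (``d`` may
    be ``numpy.inf`` for the orthographic limit, where the foreshortening
    ratio tends to ``cos(gamma) = a/b``).

    Returns the positive and negative branch, in radians.
    """
    if not (0 < a <= b):
        raise ValueError("require 0 < a <= b (semi-minor first)")
    if not d > 0:
        raise ValueError("require d > 0")
    ratio2 = (a / b) ** 2
    denom = 1.0 + (0.0 if np.isinf(d) else (a / d) ** 2)
    s = np.sqrt((1.0 - ratio2) / denom)
    gamma = float(np.arcsin(min(1.0, s)))
    return gamma, -gamma


def _circle_section(w: np.ndarray, sign: float) -> tuple[np.ndarray, np.ndarray, float]:
    """Circle section of the canonical cone ``l1 x^2 + l2 y^2 + l3 z^2 = 0``.

    Returns (plane normal, circle centre for plane offset 1, circle radius
    for plane offset 1), all in the aligned frame.  ``sign`` selects the
    +gamma / -gamma branch.
    """
    l1, l2, l3 = w
    g = np.sqrt(max(0.0, (l1 - l2) / (l1 - l3)))
    h = np.sqrt((l2 - l3) / (l1 - l3))
    n = np.array([sign * g, 0.0, h])
    u = np.array([h, 0.0, -sign * g])  # in-plane direction
    # plane n.x = 1; cone restricted to it is l2[(s - s*)^2 + t^2] + f0
    s_star = -(l1 * n[0] * u[0] + l3 * n[2] * u[2]) / l2
    centre = n + s_star * u
    f0 = l1 * centre[0] ** 2 + l2 * centre[1] ** 2 + l3 * centre[2] ** 2
    radius = np.sqrt(max(0.0, -f0 / l2))
    return n, centre, radius


def interpret_circle(e: ImageEllipse, intrinsics: CameraIntrinsics) -> tuple:
    """Both 3D circle interpretations (real and imaginary) of an ellipse.

    Returns a pair of :class:`CircleInterpretation`, ordered by increasing
    eccentricity shift (the first label is provisionally ``"real"``).
    For a circle parallel to the image plane both interpretations
    coincide and the centre ray passes through the ellipse centre.
    """
    cone = align_cone(e, intrinsics)
    R_axis_to_cam = cone.rotation_to_axis.T
    w = cone.eigenvalues
    gamma = gamma_from_ellipse(cone.semi_minor, cone.semi_major,
                               intrinsics.d_mm)[0]
    interps = []
    for sign in (+1.0, -1.0):
        n_a, c_a, r_a = _circle_section(w, sign)
        if r_a <= 0:
            raise GeometryError("degenerate circle section")
        c_cam = R_axis_to_cam @ (c_a / r_a)  # centre for unit physical radius
        if c_cam[2] < 0:
            c_cam = -c_cam
        n_cam = R_axis_to_cam @ n_a
        ray = Ray(np.zeros(3), c_cam)
        if n_cam @ ray.direction > 0:  # orient normal towards the camera
            n_cam = -n_cam
        # corrected projected centre on the image plane
        proj = intrinsics.d_mm * c_cam[:2] / c_cam[2]
        corrected_px = intrinsics.metric_to_pixel(proj)
        shift = float(np.linalg.norm(corrected_px - e.centre))
        interps.append(
            CircleInterpretation(
                centre_ray=ray,
                normal=n_cam,
                label="",
                gamma=gamma,
                centre_unit_radius=c_cam,
                centre_shift_px=shift,
            )
        )
    interps.sort(key=lambda it: it.centre_shift_px)
    first = CircleInterpretation(
        centre_ray=interps[0].centre_ray, normal=interps[0].normal,
        label="real", gamma=interps[0].gamma,
        centre_unit_radius=interps[0].centre_unit_radius,
        centre_shift_px=interps[0].centre_shift_px)
    second = CircleInterpretation(
        centre_ray=interps[1].centre_ray, normal=interps[1].normal,
        label="imaginary", gamma=interps[1].gamma,
        centre_unit_radius=interps[1].centre_unit_radius,
        centre_shift_px=interps[1].centre_shift_px)
    return first, second
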