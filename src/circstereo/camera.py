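"""Pinhole camera model shared by detection, pose estimation and reconstruction.

Conventions
-----------
* Camera frame: right-handed, ``+Z`` along the viewing axis, image ``X``
  right, image ``Y`` down.  The projection centre ``O`` is the origin.
* The image plane sits at ``z = d`` millimetres in front of ``O``, where
  ``d = principal_distance * pixel_pitch``.
* All geometry is carried in millimetres; pixels are converted at the
  camera boundary through ``pixel_pitch``.
* Distortion follows the standard Brown model (radial ``k1, k2`` plus
  tangential ``p1, p2``) applied to normalized coordinates.  An empty
  coefficient list is an ideal pinhole.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import yaml

from .errors import DegenerateProjectionError

__all__ = [
    "CameraIntrinsics",
    "Ray",
    "RigidTransform",
    "project",
    "backproject_ray",
    "load_intrinsics",
    "save_intrinsics",
]


@dataclass(frozen=True)
class CameraIntrinsics:
    """Pre-calibrated internal parameters of one camera.

    Attributes
    ----------
    principal_point : (2,) array, pixels
        Foot of the optical axis on the image (symbol ``E``).
    principal_distance : float, pixels
        Distance from the projection centre ``O`` to the image plane,
        expressed in pixels (symbol ``d`` once multiplied by the pitch).
    pixel_pitch : float, mm/pixel
        Physical size of one pixel; converts image quantities to mm.
    distortion : tuple of float
        ``(k1, k2, p1, p2)`` Brown coefficients; empty for an ideal pinhole.
    image_size : (2,) ints, pixels
        Width, height.
    """

    principal_point: np.ndarray
    principal_distance: float
    pixel_pitch: float
    distortion: tuple = ()
    image_size: tuple = (1600, 1200)

    def __post_init__(self):
        pp = np.asarray(self.principal_point, dtype=float)
        object.__setattr__(self, "principal_point", pp)
        object.__setattr__(self, "distortion", tuple(float(c) for c in self.distortion))
        if self.principal_distance <= 0:
            raise ValueError("principal_distance must be positive")
        if self.pixel_pitch <= 0:
            raise ValueError("pixel_pitch must be positive")
        w, h = self.image_size
        if not (0 <= pp[0] <= w and 0 <= pp[1] <= h):
            raise ValueError("principal point outside image bounds")

    @property
    def d_mm(self) -> float:
        """Metric distance from ``O`` to the image plane."""
        return self.principal_distance * self.pixel_pitch

    # -- pixel <-> metric image-plane coordinates (relative to E) ----------
    def pixel_to_metric(self, pix) -> np.ndarray:
        """Pixels -> mm on the image plane, origin at the principal point."""
        pix = np.asarray(pix, dtype=float)
        return (pix - self.principal_point) * self.pixel_pitch

    def metric_to_pixel(self, xy_mm) -> np.ndarray:
        xy_mm = np.asarray(xy_mm, dtype=float)
        return xy_mm / self.pixel_pitch + self.principal_point


@dataclass(frozen=True)
class Ray:
    """Half-line ``origin + s * direction`` (s >= 0), in mm."""

    origin: np.ndarray
    direction: np.ndarray

    def __post_init__(self):
        o = np.asarray(self.origin, dtype=float)
        d = np.asarray(self.direction, dtype=float)
        n = np.linalg.norm(d)
        if n == 0:
            raise ValueError("zero ray direction")
        object.__setattr__(self, "origin", o)
        object.__setattr__(self, "direction", d / n)

    def point_at(self, s: float) -> np.ndarray:
        return self.origin + s * self.direction


@dataclass(frozen=True)
class RigidTransform:
    """Proper rigid motion ``x -> R x + t`` (rotation + translation, mm)."""

    rotation: np.ndarray
    translation: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self):
        R = np.asarray(self.rotation, dtype=float)
        t = np.asarray(self.translation, dtype=float)
        if R.shape != (3, 3):
            raise ValueError("rotation must be 3x3")
        if not np.allclose(R.T @ R, np.eye(3), atol=1e-8):
            raise ValueError("rotation is not orthonormal")
        if np.linalg.det(R) < 0:
            raise ValueError("rotation must have det +1")
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "translation", t)

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))

    def apply(self, points) -> np.ndarray:
        points = np.asarray(points, dtype=float)
        return points @ self.rotation.T + self.translation

    def apply_ray(self, ray: Ray) -> Ray:
        return Ray(self.apply(ray.origin), self.rotation @ ray.direction)

    def inverse(self) -> "RigidTransform":
        return RigidTransform(self.rotation.T, -self.rotation.T @ self.translation)

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """``self @ other``: apply *other* first, then *self*."""
        return RigidTransform(
            self.rotation @ other.rotation,
            self.rotation @ other.translation + self.translation,
        )

    def __matmul__(self, other: "RigidTransform") -> "RigidTransform":
        return self.compose(other)


# ---------------------------------------------------------------------------
# distortion helpers (normalized coordinates x/z, y/z)

def _distort(nxy: np.ndarray, coeffs) -> np.ndarray:
    if not coeffs:
        return nxy
    k1, k2, p1, p2 = (list(coeffs) + [0.0] * 4)[:4]
    x, y = nxy[..., 0], nxy[..., 1]
    r2 = x * x + y * y
    radial = 1 + k1 * r2 + k2 * r2 * r2
    xd = x * radial + 2 * p1 * x * y + p2 * (r2 + 2 * x * x)
    yd = y * radial + p1 * (r2 + 2 * y * y) + 2 * p2 * x * y
    return np.stack([xd, yd], axis=-1)


def _undistort(nxy: np.ndarray, coeffs, n_iter: int = 20) -> np.ndarray:
    if not coeffs:
        return nxy
    # fixed-point iteration; converges for mild webcam distortion
    guess = nxy.copy()
    for _ in range(n_iter):
        guess = guess + (nxy - _distort(guess, coeffs))
    return guess


def project(point3, intrinsics: CameraIntrinsics) -> np.ndarray:
    """Perspective projection of camera-frame point(s) [mm] to pixels.

    Raises
    ------
    DegenerateProjectionError
        If any point has non-positive depth.
    """
    p = np.asarray(point3, dtype=float)
    z = p[..., 2]
    if np.any(z <= 0):
        raise DegenerateProjectionError("point at or behind the projection centre")
    nxy = p[..., :2] / z[..., None]
    nxy = _distort(nxy, intrinsics.distortion)
    return intrinsics.principal_point + intrinsics.principal_distance * nxy


def backproject_ray(pixel, intrinsics: CameraIntrinsics) -> Ray:
    """Ray from the projection centre ``O`` through an image pixel."""
    pix = np.asarray(pixel, dtype=float)
    nxy = (pix - intrinsics.principal_point) / intrinsics.principal_distance
    nxy = _undistort(nxy, intrinsics.distortion)
    direction = np.array([nxy[0], nxy[1], 1.0])
    return Ray(np.zeros(3), direction)


# ---------------------------------------------------------------------------
# intrinsics file I/O

def load_intrinsics(path) -> CameraIntrinsics:
    """Read a per-camera intrinsics YAML/JSON file."""
    with open(path) as fh:
        data = yaml.safe_load(fh)
    return CameraIntrinsics(
        principal_point=np.asarray(data["principal_point"], dtype=float),
        principal_distance=float(data["principal_distance_px"]),
        pixel_pitch=float(data["pixel_pitch_mm"]),
        distortion=tuple(data.get("distortion", []) or []),
        image_size=tuple(data.get("image_size", (1600, 1200))),
    )


def save_intrinsics(intr: CameraIntrinsics, path) -> None:
    data = {
        "principal_point": [float(v) for v in intr.principal_point],
        "principal_distance_px": float(intr.principal_distance),
        "pixel_pitch_mm": float(intr.pixel_pitch),
        "distortion": list(intr.distortion),
        "image_size": [int(v) for v in intr.image_size],
    }
    with open(path, "w") as fh:
        yaml.safe_dump(data, fh)
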