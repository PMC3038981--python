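"""Synthetic stereo rig and marker world with exact ground truth.

Emulates the physical apparatus of a small-volume stereophotogrammetric
tracker: two pre-calibrated 1600x1200 webcams whose viewing axes cross
at ~40 degrees on the target, rolled by 90 degrees about their axes; a
planar four-circle fiducial plate (diameter-5-mm circles) that defines
the measurement frame; and plates carrying 1-2 mm circular markers
(8x8 grids at 10 mm pitch, or 15-mm squares of four circles).

Two render modes are provided:

* ``analytic`` — the exact perspective image conic of every circle, as
  :class:`~circstereo.detect.ImageEllipse` parameters (optionally
  perturbed by seeded Gaussian noise on the centres), bypassing pixel
  detection entirely;
* ``raster`` — 8-bit images with anti-aliased dark discs (8x
  supersampling, box filter) plus optional Gaussian intensity noise and
  a linear illumination gradient.

Every scene carries a full ground-truth manifest (3D centre, normal,
per-camera true projected centre, fiducial pose per camera), so every
other module can be tested against an independent forward model.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .camera import CameraIntrinsics, RigidTransform, project
from .detect import ImageEllipse
from .errors import DegenerateProjectionError
from .fiducial import FiducialModel, default_fiducial

__all__ = [
    "NoiseModel",
    "RigConfig",
    "ScenarioSpec",
    "SceneCircle",
    "Scene",
    "CameraView",
    "default_intrinsics",
    "project_circle_exact",
    "render",
    "run_protocol",
    "grid_plate",
    "square_plate",
]

#: rotation-test step size (degrees) of the milling-unit headpiece
ROTATION_STEP_DEG = 2.25
#: translation-test displacement amounts (mm)
TRANSLATION_AMOUNTS = (0.5, 1.0, 5.0)
#: plate tilt angles (degrees) for the rotating-plate / rotating-camera tests
TILT_ANGLES_DEG = (-60.0, -45.0, -30.0, -15.0, 15.0, 30.0, 45.0, 60.0)


def default_intrinsics() -> CameraIntrinsics:
    """Bundled webcam-like intrinsics.

    1600x1200 pixels; the principal distance (3400 px at a 4 um pitch,
    i.e. a 13.6 mm focal length) makes a 2 mm marker at the 300 mm
    working distance span ~23 px — the zoomed imaging regime — while
    keeping the whole 8x8 grid in frame throughout the evaluation
    protocols.
    """
    return CameraIntrinsics(
        principal_point=np.array([799.5, 599.5]),
        principal_distance=3400.0,
        pixel_pitch=0.004,
        distortion=(),
        image_size=(1600, 1200),
    )


@dataclass(frozen=True)
class NoiseModel:
    """Seed-controlled perturbations of the rendered observations.

    ``centre_sigma_px`` jitters analytic ellipse centres (i.i.d.
    Gaussian per coordinate).  ``pixel_sigma`` adds Gaussian intensity
    noise to raster images (8-bit counts); across the ~1-px anti-aliased
    edge profile of ~200 counts this translates to an edge-position
    jitter of roughly ``pixel_sigma / 200`` px.  ``illumination_slope``
    applies a linear brightness gradient across the raster frame.
    """

    centre_sigma_px: float = 0.0
    pixel_sigma: float = 0.0
    illumination_slope: float = 0.0


def _rot_axis(axis: str, angle_deg: float) -> np.ndarray:
    a = np.deg2rad(angle_deg)
    c, s = np.cos(a), np.sin(a)
    if axis == "x":
        return np.array([[1, 0, 0], [0, c, -s], [0, s, c]], dtype=float)
    if axis == "y":
        return np.array([[c, 0, s], [0, 1, 0], [-s, 0, c]], dtype=float)
    if axis == "z":
        return np.array([[c, -s, 0], [s, c, 0], [0, 0, 1]], dtype=float)
    raise ValueError(f"unknown axis {axis!r}")


@dataclass(frozen=True)
class RigConfig:
    """Geometry of the stereo rig, in the fiducial frame.

    The fiducial plate lies in the plane ``z = 0`` with its circles
    facing the cameras (+z).  The two cameras sit at ``working_distance``
    from ``camera_target`` (the centre of the measurement volume, above
    the fiducial — the fiducial itself images in the lower part of each
    field of view), their viewing axes crossing there with
    ``camera_axis_angle`` between them, each rolled ``camera_roll``
    degrees about its own axis.
    """

    camera_axis_angle: float = 40.0   # degrees between the two viewing axes
    working_distance: float = 300.0   # mm, camera to the target point
    camera_roll: float = 90.0         # degrees about the viewing axis
    camera_target: tuple = (0.0, -38.0, 10.0)  # mm, fiducial frame
    intrinsics: tuple = ()
    fiducial: FiducialModel = field(default_factory=default_fiducial)
    volume: float = 100.0             # mm, nominal cubic measurement volume

    def __post_init__(self):
        if not self.intrinsics:
            intr = default_intrinsics()
            object.__setattr__(self, "intrinsics", (intr, intr))

    def camera_poses(self) -> tuple:
        """Fiducial-to-camera rigid transforms for the two cameras."""
        poses = []
        half = self.camera_axis_angle / 2.0
        target = np.asarray(self.camera_target, dtype=float)
        for sign in (-1.0, +1.0):
            ha = np.deg2rad(sign * half)
            pos = target + self.working_distance * np.array(
                [np.sin(ha), 0.0, np.cos(ha)])
            z = (target - pos) / np.linalg.norm(target - pos)
            up = np.array([0.0, 1.0, 0.0])        # image y points "down"
            x = np.cross(up, z)
            x /= np.linalg.norm(x)
            y = np.cross(z, x)
            R_wc = np.vstack([x, y, z])
            R = _rot_axis("z", self.camera_roll) @ R_wc
            poses.append(RigidTransform(R, -R @ pos))
        return tuple(poses)


@dataclass(frozen=True)
class SceneCircle:
    """One physical circle, ground truth in the fiducial frame."""

    marker_id: object
    centre: np.ndarray
    normal: np.ndarray
    radius: float
    kind: str = "marker"     # "fiducial" | "marker"
    group: str = ""          # plate identifier

    def __post_init__(self):
        object.__setattr__(self, "centre", np.asarray(self.centre, dtype=float))
        n = np.asarray(self.normal, dtype=float)
        object.__setattr__(self, "normal", n / np.linalg.norm(n))


@dataclass(frozen=True)
class Scene:
    """A static configuration of circles plus protocol metadata."""

    scene_id: str
    circles: tuple
    meta: dict = field(default_factory=dict)

    def truth_positions(self, kind: str = "marker") -> dict:
        return {c.marker_id: c.centre for c in self.circles if c.kind == kind}


@dataclass(frozen=True)
class CameraView:
    """Per-camera render result (analytic ellipses and/or raster image)."""

    camera_id: int
    ellipses: tuple            # visible ImageEllipse, detection-style order
    marker_ids: tuple          # ground-truth id per ellipse (same order)
    true_centres_px: tuple     # true projected circle centre per ellipse
    image: np.ndarray = None   # uint8 raster, raster mode only


# ---------------------------------------------------------------------------
# exact projection of a circle

def _conic_to_ellipse_params(A: np.ndarray):
    """Homogeneous 2D conic -> (centre, semi-minor, semi-major, angle of major)."""
    A2 = A[:2, :2]
    g = A[:2, 2]
    centre = np.linalg.solve(A2, -g)
    mu = centre @ A2 @ centre + 2 * g @ centre + A[2, 2]
    M = A2 / (-mu)
    w, V = np.linalg.eigh(M)
    if np.any(w <= 0):
        raise DegenerateProjectionError("projected conic is not an ellipse")
    axes = 1.0 / np.sqrt(w)  # descending: axes[0] = major
    alpha = np.arctan2(V[1, 0], V[0, 0]) % np.pi
    return centre, float(axes[1]), float(axes[0]), float(alpha)


def project_circle_exact(centre, normal, radius: float,
                         intrinsics: CameraIntrinsics):
    """Exact image of a camera-frame circle: conic and true centre pixel.

    Returns ``(ImageEllipse, true_centre_px)`` where the ellipse is the
    exact perspective image of the circle and ``true_centre_px`` the
    perspective projection of its 3D centre — the two differ by the
    eccentricity offset whenever the circle is tilted.

    Raises
    ------
    DegenerateProjectionError
        Circle behind the camera, or circle plane through ``O``.
    """
    c = np.asarray(centre, dtype=float)
    n = np.asarray(normal, dtype=float)
    n = n / np.linalg.norm(n)
    if c[2] <= 0:
        raise DegenerateProjectionError("circle behind the camera")
    if abs(n @ c) < 1e-9 * np.linalg.norm(c):
        raise DegenerateProjectionError("circle plane passes through O")
    t = np.array([1.0, 0, 0]) if abs(n[0]) < 0.9 else np.array([0, 1.0, 0])
    u = np.cross(n, t)
    u /= np.linalg.norm(u)
    v = np.cross(n, u)
    d = intrinsics.d_mm
    # homography (circle-plane unit disc frame) -> metric image plane
    H = np.array([[d, 0, 0], [0, d, 0], [0, 0, 1.0]]) @ \
        np.column_stack([radius * u, radius * v, c])
    Hinv = np.linalg.inv(H)
    A = Hinv.T @ np.diag([1.0, 1.0, -1.0]) @ Hinv
    A = (A + A.T) / 2
    ctr_mm, amin_mm, amaj_mm, alpha = _conic_to_ellipse_params(A)
    ellipse = ImageEllipse(
        centre=intrinsics.metric_to_pixel(ctr_mm),
        semi_minor=amin_mm / intrinsics.pixel_pitch,
        semi_major=amaj_mm / intrinsics.pixel_pitch,
        orientation=alpha,
        n_edge_pixels=0,
    )
    true_px = project(c, intrinsics)
    return ellipse, true_px


def _visible(e: ImageEllipse, intrinsics: CameraIntrinsics,
             margin: float = 2.0) -> bool:
    w, h = intrinsics.image_size
    r = e.semi_major + margin
    cx, cy = e.centre
    return (r <= cx <= w - 1 - r) and (r <= cy <= h - 1 - r)


# ---------------------------------------------------------------------------
# plate builders

def grid_plate(nrows: int = 8, ncols: int = 8, spacing: float = 10.0,
               marker_diameter: float = 2.0,
               pose: RigidTransform = None, group: str = "grid"):
    """8x8-style grid of circles on a plate; ids are ``(row, col)``.

    ``pose`` maps plate coordinates (grid centred at the plate origin,
    z = 0, normal +z) into the fiducial frame.
    """
    pose = pose or RigidTransform.identity()
    circles = []
    r0, c0 = (nrows - 1) / 2.0, (ncols - 1) / 2.0
    for r in range(nrows):
        for c in range(ncols):
            local = np.array([(c - c0) * spacing, (r - r0) * spacing, 0.0])
            circles.append(SceneCircle(
                marker_id=(r, c),
                centre=pose.apply(local),
                normal=pose.rotation @ np.array([0.0, 0.0, 1.0]),
                radius=marker_diameter / 2.0,
                kind="marker",
                group=group,
            ))
    return circles


def square_plate(side: float = 15.0, marker_diameter: float = 2.0,
                 pose: RigidTransform = None, group: str = "plate"):
    """Four circles on the corners of a square (ids ``group:0..3``)."""
    pose = pose or RigidTransform.identity()
    h = side / 2.0
    corners = [(-h, -h), (h, -h), (h, h), (-h, h)]
    return [
        SceneCircle(
            marker_id=f"{group}:{k}",
            centre=pose.apply(np.array([x, y, 0.0])),
            normal=pose.rotation @ np.array([0.0, 0.0, 1.0]),
            radius=marker_diameter / 2.0,
            kind="marker",
            group=group,
        )
        for k, (x, y) in enumerate(corners)
    ]


def _fiducial_circles(model: FiducialModel):
    return [
        SceneCircle(marker_id=f"fid:{k}", centre=np.array([x, y, 0.0]),
                    normal=np.array([0.0, 0.0, 1.0]),
                    radius=model.circle_diameter / 2.0,
                    kind="fiducial", group="fiducial")
        for k, (x, y) in enumerate(model.circle_centres)
    ]


# ---------------------------------------------------------------------------
# rendering

def render(scene: Scene, rig: RigConfig, mode: str = "analytic",
           noise: NoiseModel = None, rng: np.random.Generator = None):
    """Render a scene through both cameras.

    Returns a list of two :class:`CameraView`.  Circles outside a
    camera's field of view are recorded as not visible (simply absent
    from that view) rather than raising.  With a fixed ``rng`` seed the
    output is bit-identical across runs.
    """
    noise = noise or NoiseModel()
    rng = rng if rng is not None else np.random.default_rng(0)
    views = []
    for cam_id, (pose, intr) in enumerate(zip(rig.camera_poses(), rig.intrinsics)):
        ellipses, ids, true_pxs = [], [], []
        for circ in scene.circles:
            c_cam = pose.apply(circ.centre)
            n_cam = pose.rotation @ circ.normal
            try:
                e, true_px = project_circle_exact(c_cam, n_cam, circ.radius, intr)
            except DegenerateProjectionError:
                continue
            if not _visible(e, intr):
                continue
            if mode == "analytic" and noise.centre_sigma_px > 0:
                e = replace(e, centre=e.centre
                            + rng.normal(0.0, noise.centre_sigma_px, 2))
            ellipses.append(e)
            ids.append(circ.marker_id)
            true_pxs.append(true_px)
        image = None
        if mode == "raster":
            image = _rasterize(ellipses, intr, noise, rng)
        views.append(CameraView(camera_id=cam_id, ellipses=tuple(ellipses),
                                marker_ids=tuple(ids),
                                true_centres_px=tuple(true_pxs), image=image))
    return views


def _rasterize(ellipses, intrinsics: CameraIntrinsics, noise: NoiseModel,
               rng: np.random.Generator, background: float = 230.0,
               foreground: float = 25.0, supersample: int = 8) -> np.ndarray:
    """Anti-aliased dark discs on a light background, 8-bit."""
    w, h = intrinsics.image_size
    img = np.full((h, w), background, dtype=float)
    if noise.illumination_slope:
        xs = np.arange(w) / max(w - 1, 1)
        img += noise.illumination_slope * background * (xs - 0.5)[None, :]
    for e in ellipses:
        u = np.array([np.cos(e.orientation), np.sin(e.orientation)])
        v = np.array([-u[1], u[0]])
        A2 = (np.outer(u, u) / e.semi_major ** 2
              + np.outer(v, v) / e.semi_minor ** 2)
        r = e.semi_major + 2
        x0 = max(0, int(np.floor(e.centre[0] - r)))
        x1 = min(w - 1, int(np.ceil(e.centre[0] + r)))
        y0 = max(0, int(np.floor(e.centre[1] - r)))
        y1 = min(h - 1, int(np.ceil(e.centre[1] + r)))
        if x1 < x0 or y1 < y0:
            continue
        ss = supersample
        sub = (np.arange(ss) + 0.5) / ss - 0.5
        xs = (np.arange(x0, x1 + 1)[:, None] + sub[None, :]).ravel() - e.centre[0]
        ys = (np.arange(y0, y1 + 1)[:, None] + sub[None, :]).ravel() - e.centre[1]
        qxx, qyy, qxy = A2[0, 0], A2[1, 1], A2[0, 1]
        inside = (qxx * xs[None, :] ** 2 + qyy * ys[:, None] ** 2
                  + 2 * qxy * xs[None, :] * ys[:, None]) <= 1.0
        cov = inside.reshape(len(ys) // ss, ss, len(xs) // ss, ss).mean(axis=(1, 3))
        patch = img[y0:y1 + 1, x0:x1 + 1]
        patch -= cov * (patch - foreground)
    if noise.pixel_sigma > 0:
        img += rng.normal(0.0, noise.pixel_sigma, img.shape)
    return np.clip(np.round(img), 0, 255).astype(np.uint8)


# ---------------------------------------------------------------------------
# evaluation protocols

@dataclass(frozen=True)
class ScenarioSpec:
    """Which evaluation protocol to generate, and under what conditions.

    ``kind`` is one of ``grid | testA | testB | testC | rotation |
    translation | custom``.  Defaults reproduce the study conditions:
    10-mm grid pitch, ~10-mm camera retreat steps, plate tilts up to
    +/- 60 degrees, 2.25-degree rotation steps over +/- 45 degrees, and
    0.5 / 1 / 5 mm translations, each repeated five times.
    """

    kind: str = "grid"
    marker_diameter: float = 2.0
    repeats: int = 5
    grid_shape: tuple = (8, 8)
    grid_spacing: float = 10.0
    retreat_step: float = 10.0          # mm per Test-A camera position
    n_positions: int = 8                # Test-A camera positions
    tilt_angles: tuple = TILT_ANGLES_DEG
    rotation_step: float = ROTATION_STEP_DEG
    rotation_range: float = 45.0        # degrees, +/- from zero
    translation_amounts: tuple = TRANSLATION_AMOUNTS
    axes: tuple = ("x", "y", "z")
    plate_offset: tuple = (0.0, -57.0, 10.0)  # grid-plate centre, fiducial frame
    noise: NoiseModel = field(default_factory=NoiseModel)
    seed: int = 0


def _plate_pose(spec: ScenarioSpec, R: np.ndarray = None,
                extra_t=(0.0, 0.0, 0.0), centre=None) -> RigidTransform:
    """Plate-to-fiducial pose: rotation about the plate centre, then offset."""
    R = np.eye(3) if R is None else R
    centre = np.asarray(centre if centre is not None else spec.plate_offset,
                        dtype=float)
    return RigidTransform(R, centre + np.asarray(extra_t, dtype=float))


def run_protocol(spec: ScenarioSpec, rig: RigConfig):
    """Generate the full scene series of an evaluation protocol.

    Every scene includes the fiducial circles and carries its reference
    values in ``scene.meta``; the series is fully determined by
    ``(spec, rig)`` including the seed.
    """
    fid = _fiducial_circles(rig.fiducial)
    scenes = []

    def add(scene_id, circles, **meta):
        scenes.append(Scene(scene_id=scene_id, circles=tuple(fid + circles),
                            meta=dict(meta)))

    stationary_c = np.asarray(spec.plate_offset) + np.array([-13.0, 0.0, 0.0])
    moving_c = np.asarray(spec.plate_offset) + np.array([13.0, 0.0, 0.0])

    if spec.kind == "grid":
        add("grid", grid_plate(*spec.grid_shape, spec.grid_spacing,
                               spec.marker_diameter, _plate_pose(spec)),
            kind="grid", reference_spacing=spec.grid_spacing)

    elif spec.kind in ("testA", "testB", "testC"):
        nr, nc = spec.grid_shape
        for rep in range(spec.repeats):
            if spec.kind == "testA":
                # the rig (cameras + fiducial) retreats from the plate along
                # Z_obj; in the fiducial frame the plate recedes instead
                steps = [("pos", k, _plate_pose(
                    spec, extra_t=(0, 0, -spec.retreat_step * k)))
                    for k in range(spec.n_positions)]
            else:
                axis = "x" if spec.kind == "testB" else "y"
                steps = [("tilt", ang, _plate_pose(spec, _rot_axis(axis, ang)))
                         for ang in spec.tilt_angles]
            for tag, val, pose in steps:
                add(f"{spec.kind}-{tag}{val}-r{rep}",
                    grid_plate(nr, nc, spec.grid_spacing,
                               spec.marker_diameter, pose),
                    kind=spec.kind, step=val, repeat=rep,
                    reference_spacing=spec.grid_spacing)

    elif spec.kind == "rotation":
        n_steps = int(round(spec.rotation_range / spec.rotation_step))
        angles = spec.rotation_step * np.arange(-n_steps, n_steps + 1)
        for axis in spec.axes:
            for ang in angles:
                circles = (square_plate(marker_diameter=spec.marker_diameter,
                                        pose=_plate_pose(spec, centre=stationary_c),
                                        group="stationary")
                           + square_plate(marker_diameter=spec.marker_diameter,
                                          pose=_plate_pose(
                                              spec, _rot_axis(axis, ang),
                                              centre=moving_c),
                                          group="moving"))
                add(f"rot-{axis}-{ang:+07.2f}", circles,
                    kind="rotation", axis=axis, angle=float(ang),
                    reference_step=spec.rotation_step)

    elif spec.kind == "translation":
        unit = {"x": np.array([1.0, 0, 0]), "y": np.array([0, 1.0, 0]),
                "z": np.array([0, 0, 1.0])}
        for rep in range(spec.repeats):
            conditions = [("zero", None, 0.0)]
            conditions += [(axis, axis, amt) for axis in spec.axes
                           for amt in spec.translation_amounts]
            for tag, axis, amt in conditions:
                shift = amt * unit[axis] if axis else np.zeros(3)
                circles = (square_plate(marker_diameter=spec.marker_diameter,
                                        pose=_plate_pose(spec, centre=stationary_c),
                                        group="stationary")
                           + square_plate(marker_diameter=spec.marker_diameter,
                                          pose=_plate_pose(
                                              spec, extra_t=shift,
                                              centre=moving_c),
                                          group="moving"))
                add(f"trans-{tag}-{amt}-r{rep}", circles,
                    kind="translation", axis=axis, amount=float(amt),
                    repeat=rep, reference_shift=tuple(shift))

    else:
        raise ValueError(f"unknown protocol kind {spec.kind!r}")

    return scenes
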