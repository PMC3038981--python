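"""End-to-end scene processing and protocol evaluation.

``process_views`` runs the measurement chain on one stereo pair of
ellipse observations (analytic, or detected from images): identify the
four fiducial ellipses, estimate each camera's pose, interpret every
marker ellipse as its two candidate circles, match markers across the
views and triangulate them in the fiducial frame.

The ``evaluate_*`` functions score protocol runs of the synthetic
generator against their references (grid spacing, commanded
translations, commanded rotation steps).  Reconstructed markers are
associated with ground-truth identities by nearest true position, which
is evaluation bookkeeping only — the measurement itself never consults
the manifest.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .camera import backproject_ray
from .circle import interpret_circle
from .detect import detect_markers
from .errors import CircstereoError
from .fiducial import estimate_pose
from .kinematics import (
    attitude_decompose,
    grid_adjacency,
    inter_marker_distances,
    rigid_body_transform,
)
from .stereo import match_markers
from .synthetic import RigConfig, Scene, render

__all__ = [
    "SceneReconstruction",
    "split_fiducial",
    "process_views",
    "reconstruct_scene",
    "evaluate_grid_scenes",
    "evaluate_translation_scenes",
    "evaluate_rotation_scenes",
]


@dataclass(frozen=True)
class SceneReconstruction:
    """Result of processing one stereo pair."""

    points: list               # MarkerPoint3D, fiducial frame
    poses: tuple               # per-camera PoseSolution
    unmatched: tuple           # (left ids, right ids)

    @property
    def mean_gap(self) -> float:
        return float(np.mean([p.gap for p in self.points])) if self.points else 0.0


def split_fiducial(ellipses):
    """Separate the four fiducial ellipses from tracked-marker ellipses.

    The fiducial circles (diameter 5 mm) image larger than the 1-2 mm
    tracked markers, so the four largest ellipses (by semi-major axis)
    are taken as the fiducial.
    """
    if len(ellipses) < 4:
        raise CircstereoError(
            f"need at least 4 ellipses for the fiducial, got {len(ellipses)}")
    order = np.argsort([-e.semi_major for e in ellipses])
    fid_idx = set(order[:4].tolist())
    fid = [ellipses[i] for i in order[:4]]
    markers = [e for i, e in enumerate(ellipses) if i not in fid_idx]
    return fid, markers


def _marker_interpretations(ellipses, intrinsics, use_ecc_correction=True):
    pairs = []
    for e in ellipses:
        pair = interpret_circle(e, intrinsics)
        if not use_ecc_correction:
            # ablation: ignore the eccentricity and use the raw ellipse
            # centre ray for both branches (normals kept for matching)
            from dataclasses import replace
            ray = backproject_ray(e.centre, intrinsics)
            pair = tuple(replace(it, centre_ray=ray) for it in pair)
        pairs.append(pair)
    return pairs


#: fiducial branch-selection tolerances for pixel-detected (raster) input,
#: where edge discretization perturbs the circle normals by a few mrad
RASTER_TOL_NORMAL = 0.02
RASTER_TOL_PLANE = 0.02


def process_views(ellipses_per_camera, rig: RigConfig,
                  use_ecc_correction: bool = True,
                  tol_normal: float = None,
                  tol_plane_rel: float = None) -> SceneReconstruction:
    """Measurement chain on one stereo pair of ellipse lists."""
    poses = []
    marker_pairs = []
    for ellipses, intr in zip(ellipses_per_camera, rig.intrinsics):
        fid, markers = split_fiducial(list(ellipses))
        kwargs = {}
        if tol_normal is not None:
            kwargs["tol_normal"] = tol_normal
        if tol_plane_rel is not None:
            kwargs["tol_plane_rel"] = tol_plane_rel
        poses.append(estimate_pose(fid, rig.fiducial, intr, **kwargs))
        marker_pairs.append(_marker_interpretations(markers, intr,
                                                    use_ecc_correction))
    points, ul, ur = match_markers(marker_pairs[0], marker_pairs[1],
                                   poses[0], poses[1])
    return SceneReconstruction(points=points, poses=tuple(poses),
                               unmatched=(ul, ur))


def reconstruct_scene(scene: Scene, rig: RigConfig, mode: str = "analytic",
                      noise=None, rng=None, use_ecc_correction: bool = True,
                      pose_tol_normal: float = None) -> SceneReconstruction:
    """Render a synthetic scene and run the full pipeline on it.

    In raster mode the images are put through marker detection first; in
    analytic mode the exact (optionally noise-perturbed) ellipses feed
    the pipeline directly.
    """
    views = render(scene, rig, mode=mode, noise=noise, rng=rng)
    tol_plane = None
    if mode == "raster":
        per_camera = [detect_markers(v.image.astype(float)) for v in views]
        if pose_tol_normal is None:
            pose_tol_normal = RASTER_TOL_NORMAL
        tol_plane = RASTER_TOL_PLANE
    else:
        per_camera = [list(v.ellipses) for v in views]
    return process_views(per_camera, rig,
                         use_ecc_correction=use_ecc_correction,
                         tol_normal=pose_tol_normal,
                         tol_plane_rel=tol_plane)


def assign_ids(points, truth: dict, max_dist: float = 2.0) -> dict:
    """Associate reconstructed points to ground-truth ids (nearest wins)."""
    ids = list(truth.keys())
    pos = np.array([truth[i] for i in ids])
    out = {}
    for p in points:
        d = np.linalg.norm(pos - p.position, axis=1)
        k = int(np.argmin(d))
        if d[k] <= max_dist and ids[k] not in out:
            out[ids[k]] = p
    return out


# ---------------------------------------------------------------------------
# protocol scoring (from reconstructed points)

def grid_distance_errors(truth: dict, points, spacing: float,
                         grid_shape=(8, 8)) -> np.ndarray:
    """Adjacent-pair distance errors (mm) of one reconstructed grid scene."""
    labelled = assign_ids(points, truth)
    pts = {k: v.position for k, v in labelled.items()}
    adjacency = grid_adjacency(*grid_shape)
    if pts and isinstance(next(iter(pts)), str):
        # ids round-tripped through a manifest are stringified
        adjacency = [(str(i), str(j)) for i, j in adjacency]
    dists = inter_marker_distances(pts, adjacency)
    return dists - spacing


def plate_points(truth: dict, points) -> np.ndarray:
    """Reconstructed positions of one plate, in model vertex order.

    ``truth`` maps the plate's marker ids to their true positions (used
    only to associate reconstructions with identities).
    """
    labelled = assign_ids(points, truth)
    if set(labelled) != set(truth):
        raise CircstereoError("plate incompletely reconstructed")
    ids = sorted(truth.keys())
    return np.array([labelled[i].position for i in ids])


def translation_errors(records) -> np.ndarray:
    """Signed translation errors (mm) of the moving plate.

    ``records`` is an iterable of ``(meta, moving_plate_points)`` with
    the protocol metadata of each scene.  Displaced scenes are compared
    with the zero scene of the same repeat via a rigid fit; the error is
    the recovered displacement component along the commanded axis minus
    the commanded amount.
    """
    unit = {"x": np.array([1.0, 0, 0]), "y": np.array([0, 1.0, 0]),
            "z": np.array([0, 0, 1.0])}
    zero_pts, errors, labels = {}, [], []
    records = list(records)
    for meta, pts in records:
        if meta["axis"] is None:
            zero_pts[meta["repeat"]] = pts
    for meta, pts in records:
        if meta["axis"] is None:
            continue
        transform, _ = rigid_body_transform(zero_pts[meta["repeat"]], pts)
        measured = float(transform.translation @ unit[meta["axis"]])
        errors.append(measured - meta["amount"])
        labels.append(meta)
    return np.asarray(errors), labels


def rotation_errors(records):
    """Per-step rotation-magnitude errors (degrees) of the moving plate.

    Consecutive poses along each axis sweep are compared by a rigid fit;
    the attitude-vector magnitude of each step is scored against the
    commanded step angle.  Returns ``(errors, per_step_attitudes)``.
    """
    by_axis = {}
    for meta, pts in records:
        by_axis.setdefault(meta["axis"], []).append((meta["angle"], pts))
    errors, attitudes = [], []
    for axis in sorted(by_axis):
        seq = sorted(by_axis[axis], key=lambda t: t[0])
        for (a0, p0), (a1, p1) in zip(seq, seq[1:]):
            transform, _ = rigid_body_transform(p0, p1)
            att = attitude_decompose(transform)
            errors.append(att.angle - abs(a1 - a0))
            attitudes.append((axis, a0, a1, att))
    return np.asarray(errors), attitudes


# ---------------------------------------------------------------------------
# protocol evaluation (render + reconstruct + score)

def evaluate_grid_scenes(scenes, rig: RigConfig, grid_shape=(8, 8),
                         rng=None, noise=None, mode="analytic",
                         use_ecc_correction=True, pose_tol_normal=None):
    """Adjacent-pair distance errors (mm) over grid protocol scenes.

    Returns ``(errors, errors_per_scene)`` where ``errors`` pools
    measured - reference over all scenes and adjacent pairs.
    """
    per_scene = []
    for scene in scenes:
        rec = reconstruct_scene(scene, rig, mode=mode, noise=noise, rng=rng,
                                use_ecc_correction=use_ecc_correction,
                                pose_tol_normal=pose_tol_normal)
        per_scene.append(grid_distance_errors(
            scene.truth_positions("marker"), rec.points,
            scene.meta["reference_spacing"], grid_shape))
    return np.concatenate(per_scene), per_scene


def _moving_plate_record(scene, rec):
    truth = {c.marker_id: c.centre for c in scene.circles
             if c.kind == "marker" and c.group == "moving"}
    return scene.meta, plate_points(truth, rec.points)


def evaluate_translation_scenes(scenes, rig: RigConfig, rng=None, noise=None,
                                mode="analytic", use_ecc_correction=True):
    """Translation protocol: reconstruct every scene, then score."""
    records = []
    for scene in scenes:
        rec = reconstruct_scene(scene, rig, mode=mode, noise=noise, rng=rng,
                                use_ecc_correction=use_ecc_correction)
        records.append(_moving_plate_record(scene, rec))
    errors, _ = translation_errors(records)
    return errors


def evaluate_rotation_scenes(scenes, rig: RigConfig, rng=None, noise=None,
                             mode="analytic", use_ecc_correction=True):
    """Rotation protocol: reconstruct every scene, then score the steps."""
    records = []
    for scene in scenes:
        rec = reconstruct_scene(scene, rig, mode=mode, noise=noise, rng=rng,
                                use_ecc_correction=use_ecc_correction)
        records.append(_moving_plate_record(scene, rec))
    errors, _ = rotation_errors(records)
    return errors
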