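"""File-based interchange for the command-line pipeline.

A simulated (or acquired) protocol lives in a *scene directory*:

* ``cam0.yaml``, ``cam1.yaml`` — per-camera intrinsics;
* ``fiducial.yaml`` — the fiducial plate model;
* ``rig.yaml`` — stereo-rig geometry;
* per scene, either ellipse CSVs ``<scene>_cam<j>.csv`` (analytic mode or
  detection output) or raster PNGs ``<scene>_cam<j>.png``;
* ``manifest.json`` — scene list, protocol metadata and (for synthetic
  data) the ground truth used for evaluation.

Reconstruction writes one ``<scene>_markers.csv`` per scene plus a
``report.json`` with poses, residuals and unmatched markers.
"""

from __future__ import annotations

import json
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
import yaml

from .camera import load_intrinsics, save_intrinsics
from .detect import ellipses_to_frame, frame_to_ellipses
from .fiducial import load_fiducial, save_fiducial
from .stereo import MarkerPoint3D
from .synthetic import RigConfig, Scene, SceneCircle

__all__ = [
    "write_protocol_dir",
    "load_rig",
    "load_manifest",
    "manifest_scenes",
    "write_markers_csv",
    "read_markers_csv",
]


def _scene_to_json(scene: Scene) -> dict:
    return {
        "scene_id": scene.scene_id,
        "meta": scene.meta,
        "circles": [
            {
                "marker_id": str(c.marker_id),
                "centre": [float(v) for v in c.centre],
                "normal": [float(v) for v in c.normal],
                "radius": float(c.radius),
                "kind": c.kind,
                "group": c.group,
            }
            for c in scene.circles
        ],
    }


def _scene_from_json(data: dict) -> Scene:
    circles = tuple(
        SceneCircle(
            marker_id=c["marker_id"],
            centre=np.asarray(c["centre"]),
            normal=np.asarray(c["normal"]),
            radius=c["radius"],
            kind=c["kind"],
            group=c["group"],
        )
        for c in data["circles"]
    )
    return Scene(scene_id=data["scene_id"], circles=circles, meta=data["meta"])


def write_protocol_dir(out_dir, rig: RigConfig, scenes, views_per_scene,
                       mode: str, protocol_meta: dict) -> Path:
    """Write a complete scene directory for a rendered protocol."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for j, intr in enumerate(rig.intrinsics):
        save_intrinsics(intr, out / f"cam{j}.yaml")
    save_fiducial(rig.fiducial, out / "fiducial.yaml")
    with open(out / "rig.yaml", "w") as fh:
        yaml.safe_dump({
            "camera_axis_angle": rig.camera_axis_angle,
            "working_distance": rig.working_distance,
            "camera_roll": rig.camera_roll,
            "camera_target": list(rig.camera_target),
            "volume": rig.volume,
        }, fh)
    manifest = {"mode": mode, "protocol": protocol_meta, "scenes": []}
    for scene, views in zip(scenes, views_per_scene):
        entry = _scene_to_json(scene)
        entry["views"] = []
        for v in views:
            if mode == "raster":
                fname = f"{scene.scene_id}_cam{v.camera_id}.png"
                iio.imwrite(out / fname, v.image)
            else:
                fname = f"{scene.scene_id}_cam{v.camera_id}.csv"
                ellipses_to_frame(v.ellipses, image_id=scene.scene_id,
                                  camera_id=v.camera_id).to_csv(
                    out / fname, index=False)
            entry["views"].append({
                "camera_id": v.camera_id,
                "file": fname,
                "marker_ids": [str(i) for i in v.marker_ids],
                "true_centres_px": [[float(x) for x in c]
                                    for c in v.true_centres_px],
            })
        manifest["scenes"].append(entry)
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1)
    return out


def load_rig(scene_dir) -> RigConfig:
    """Rebuild the RigConfig from a scene directory."""
    d = Path(scene_dir)
    with open(d / "rig.yaml") as fh:
        r = yaml.safe_load(fh)
    return RigConfig(
        camera_axis_angle=r["camera_axis_angle"],
        working_distance=r["working_distance"],
        camera_roll=r["camera_roll"],
        camera_target=tuple(r["camera_target"]),
        volume=r.get("volume", 100.0),
        intrinsics=(load_intrinsics(d / "cam0.yaml"),
                    load_intrinsics(d / "cam1.yaml")),
        fiducial=load_fiducial(d / "fiducial.yaml"),
    )


def load_manifest(scene_dir) -> dict:
    with open(Path(scene_dir) / "manifest.json") as fh:
        return json.load(fh)


def manifest_scenes(manifest: dict):
    """Ground-truth Scene objects recorded in a manifest."""
    return [_scene_from_json(s) for s in manifest["scenes"]]


def load_view_ellipses(scene_dir, scene_entry, mode: str):
    """Per-camera ellipse lists of one scene (reading CSVs or images)."""
    from .detect import detect_markers, read_image

    d = Path(scene_dir)
    per_camera = []
    for view in scene_entry["views"]:
        if mode == "raster":
            per_camera.append(detect_markers(read_image(d / view["file"])))
        else:
            per_camera.append(frame_to_ellipses(pd.read_csv(d / view["file"])))
    return per_camera


def write_markers_csv(points, path, scene_id: str = "") -> None:
    rows = [{
        "scene_id": scene_id,
        "marker_id": str(p.marker_id),
        "x": p.position[0], "y": p.position[1], "z": p.position[2],
        "gap_mm": p.gap,
    } for p in points]
    pd.DataFrame(rows, columns=["scene_id", "marker_id", "x", "y", "z",
                                "gap_mm"]).to_csv(path, index=False)


def read_markers_csv(path):
    df = pd.read_csv(path)
    return [
        MarkerPoint3D(position=np.array([r.x, r.y, r.z]), gap=r.gap_mm,
                      marker_id=r.marker_id)
        for r in df.itertuples()
    ]
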