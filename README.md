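# circstereo

Stereophotogrammetric measurement of small 3D motions with flat circular
markers — a compact, two-webcam motion-analysis toolkit for small
measurement volumes (~0.1 × 0.1 × 0.1 m), built for orthopaedic-research
style problems: tracking millimetre markers glued to small bones or
ligaments and resolving sub-0.01 mm displacements and sub-0.1° rotations.

## The measurement problem

Flat black circles on white background are cheap, wireless markers, but
their perspective image is an ellipse whose centre is **not** the image
of the circle's centre — the *eccentricity* of the projected circle.
`circstereo` implements the full chain that makes flat circles usable as
precision targets:

1. **Detection** — Otsu threshold, sub-pixel black/white edge contours,
   direct least-squares ellipse fit Π(c, a, b, α); markers slimmer than
   an axes ratio a/b = 0.2 (marker-plane tilt λ ≳ 78.5°) are rejected.
2. **Eccentricity correction** — the viewing cone through the projection
   centre O and the ellipse is rotated to its principal-axis form; the
   circle-plane tilt follows from

       sin γ = ± √( (1 − a²/b²) / (1 + a²/d²) ),

   with d the principal distance (mm).  Rotating the circle plane by ±γ
   yields the two circle interpretations (*real* and *imaginary*), each
   a centre ray through O plus a plane normal.
3. **Camera pose from a planar fiducial** — four coplanar circles on an
   asymmetric convex quadrangle with the coordinate origin at the
   diagonal cross point.  The perspective projections rᵢ = E + tᵢêᵢ are
   converted to orthographic ones pᵢ = E + hᵢêᵢ using the known diagonal
   ratios, the 8×4 system A s = q is solved in least squares, the scale
   is k = max(svd(S)), the rotation is completed from S/k by the
   unit-norm and det R = +1 constraints, and the two-fold ambiguity is
   resolved by perspective reprojection towards O.  The depth closure is
   z_t = d/k.
4. **Stereo reconstruction** — centre rays from both cameras are moved
   into the fiducial frame, matched across views (real-branch selection
   by normal agreement, epipolar ordering constraint, circle-size
   consistency) and triangulated as the midpoint of the common
   perpendicular; the ray–ray gap is reported per marker.
5. **Kinematics and statistics** — inter-marker distances, Kabsch rigid
   fits between marker plates, attitude-vector (axis·angle)
   decomposition onto object axes, and accuracy/precision summaries
   (mean/median error, sample SD, and the pooled RMS
   ε = √(1/(l·m·n) ΣΣΣ (d_kij − d̄_ki)²) over repeated measurements).

A synthetic stereo rig (`circstereo.synthetic`) reproduces the whole
apparatus — two 1600×1200 cameras crossing at 40°, rolled 90°, a ø5 mm
four-circle fiducial, 8×8 grids of 1–2 mm circles at 10 mm pitch, plate
rotations in 2.25° steps and 0.5/1/5 mm translations — in either exact
analytic-ellipse or anti-aliased raster mode, with full ground truth.

## Worked example

```python
import numpy as np
from circstereo import (RigConfig, ScenarioSpec, run_protocol,
                        reconstruct_scene, grid_distance_errors)

rig = RigConfig()                              # the default stereo rig
scene = run_protocol(ScenarioSpec(kind="grid"), rig)[0]
rec = reconstruct_scene(scene, rig)            # analytic, noise-free
errs = grid_distance_errors(scene.truth_positions("marker"),
                            rec.points, spacing=10.0)
print(len(rec.points), "markers,",
      f"mean |distance error| = {np.abs(errs).mean():.2e} mm")
```

prints

```
64 markers, mean |distance error| = 5.22e-14 mm
```

— all 64 grid markers are matched across the two views and the 112
adjacent 10-mm distances are recovered to numerical precision.  The same
scene pushed through the raster pipeline (8-bit images → detection →
reconstruction) lands at ~1e-3 mm, limited by sub-pixel edge
localization.

The same flow is available from the shell:

```sh
circstereo simulate --kind testB --out scenes --seed 1
circstereo reconstruct --scene-dir scenes --out recon
circstereo evaluate --scene-dir scenes --markers-dir recon --out report.json
```

`reconstruct --no-ecc-correction` ablates the eccentricity correction
(raw ellipse centres instead of corrected centre rays) — on tilted
scenes the distance error grows by several orders of magnitude, which is
the point of the method.

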