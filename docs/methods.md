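# Methods

This note documents the model behind `circstereo`, the parameter choices
that matter, what the synthetic generator does and does not emulate, and
the numerically delicate spots.

## Camera model and units

Each camera is an ideal pinhole with optional Brown distortion
(k1, k2, p1, p2), described by the principal point E (px), the principal
distance (px), the pixel pitch (mm/px) and the image size.  The camera
frame is right-handed with +Z along the viewing axis, image X right and
Y down; the image plane sits at z = d (mm), d = principal distance ×
pitch, in front of the projection centre O.  All internal geometry is
carried in millimetres; pixels are converted only at the camera
boundary.  This removes the unit ambiguity that otherwise arises when an
image length (an ellipse semi-axis) and the principal distance appear in
one formula.

## Marker detection

Dark blobs are separated with Otsu's threshold (parameter-free and
reproducible), traced with marching squares (`skimage.find_contours`),
which linearly interpolates the threshold crossing — the sub-pixel edge
model.  Contours that touch the image border are open and are dropped;
contours shorter than `min_edge_pixels = 20` are dropped because very
small blobs are dominated by uncertain edge gray values.  The conic fit
is the numerically stable direct least-squares ellipse fit
(`skimage.EllipseModel`), run on centred, isotropically rescaled
coordinates so that analytically sampled conic points are recovered to
~1e-9; the reported residual is the first-order (Sampson) geometric RMS.
An observation is accepted when its minor/major axis ratio is at least
0.2 (inclusive); in the long-working-distance limit the ratio equals
cos λ of the marker-plane tilt, so 0.2 corresponds to λ ≈ 78.5° — beyond
that the ellipse becomes too slim to fit reliably.

## Eccentricity-corrected circle centres

The ellipse and O span an oblique cone.  Writing the image conic as a
homogeneous quadric and scaling to the metric image plane gives the cone
matrix Q; its eigen-decomposition (λ1 ≥ λ2 > 0 > λ3 after sign
normalization) is exactly the "rotate the cone until its bisecting line
is the image Z-axis" construction: in the eigenframe the cone is
λ1x² + λ2y² + λ3z² = 0 and meets the image plane in an axis-aligned
ellipse centred at E with semi-axes a = d√(−λ3/λ1) ≤ b = d√(−λ3/λ2).
The planes cutting this cone in circles make the tilt angle γ with the
image plane, where sin²γ = (λ1−λ2)/(λ1−λ3); substituting the semi-axes
shows this is identically sin γ = ±√((1−a²/b²)/(1+a²/d²)) — the
closed-form tilt relation and the cone construction are the same
function, which the tests confirm against a 3600-point sampled
projection oracle.

For each sign of γ the circle section's centre is found by restricting
the quadric to the plane (a 2D quadratic whose stationary point is the
centre); mapping back through the transposed alignment rotation yields
the two interpretations: centre ray through O, unit plane normal
(oriented towards the camera), and the 3D centre per unit circle radius.
The two branches ("real" = the physical marker, "imaginary" = the
mirror solution) have nearly identical centre *rays* for thin cones;
what separates them decisively is the plane normal.  Disambiguation is
therefore deferred to the four-circle coplanarity test (fiducial) or to
the agreement of normals between the two cameras (tracked markers); the
single-view labels are provisional (ordered by the eccentricity shift).

## Fiducial pose (planar scaled-orthographic fit)

The fiducial is four ø5 mm circles at the vertices of an asymmetric
convex quadrangle (bundled default: vertices (−11,−7), (13,−9), (9,11),
(−8,14) mm re-centred on the diagonal cross point; vertex-to-cross-point
distances pairwise distinct by >5% so the vertex labelling is unique).
Branch selection maximizes mutual coplanarity of the four interpreted
circle planes (pairwise normal angle ≤ 1e-3 rad noise-free, 0.02 rad for
pixel-detected input; plane-offset spread ≤ 1–2% of the quadrangle
extent, measured on the radius-scale-free unit-radius centres).  Vertex
ordering compares the normalized distance-to-cross-point signature over
the eight cyclic/reflected orderings of the convex hull, computed on the
coplanar 3D centres (projectively undistorted), and errors out if two
orderings are not clearly separated.

The perspective→orthographic conversion assumes the image plane passes
through the 3D diagonal cross point.  Under that assumption the
constraints — p₁p₃ and p₂p₄ both pass through the image of the cross
point and are divided there at the model's diagonal ratios, with each pᵢ
on the ray E→rᵢ — form two 2×2 linear systems with a *unique* solution,
which is exactly the orthographic projection of the quadrangle scaled by
d/Z_cross.  No additional scale normalization is applied: the unique
solution is what makes the subsequent depth closure exact.  (A rig whose
cameras aim exactly at the fiducial origin puts the cross point at the
principal point and makes these systems singular; the synthetic rig
therefore aims at the measurement volume above the fiducial, which also
matches placing the fiducial in the lower part of the field of view.)

The scaled-orthographic solve stacks the 8×4 system A s = q (A from the
model plane coordinates, q from pᵢ relative to the cross point), solves
least squares (rank-revealing, with a condition-number warning above
1e8), reshapes s into the 2×2 matrix S, takes k = max singular value of
S — the top-left 2×2 block of a rotation has singular values {1, |r33|},
so k is the depth scale d/Z_cross — and completes R = S/k using the
unit-norm row/column property and det R = +1.  Exactly two right-handed
completions remain; each candidate's four centres are reprojected
perspectively and the smaller residual wins.  For an exactly
fronto-parallel plate the two completions coincide and the residuals tie
to machine precision; this raises an explicit ambiguity error (a second
camera breaks the tie).  The translation is (x_t, y_t, d)/k, i.e. the 3D
cross point.  Noise-free recovery is exact to ~1e-13 over the ±60°
working range.

## Stereo matching and triangulation

All centre rays of one camera emanate from its centre in the fiducial
frame.  Matching uses three cues:

* **Size consistency** — each interpretation fixes the 3D centre as
  O + r·k·d̂ for physical radius r; the cost of a candidate pair is the
  minimal distance between the two loci over a *common* r.  This
  subsumes the ray–ray gap and penalizes pairings whose implied circle
  radii disagree.
* **Epipolar banding + ordering** — rays are clustered by the angle of
  their epipolar plane about the baseline (band separation ~0.02 rad for
  a 10 mm grid at 300 mm; angular noise of a detected centre ~1e-5 rad),
  and within a band markers are aligned monotonically in their angle
  from the baseline (the classic ordering constraint).  This is what
  excludes phantom pairings of rays lying in one epipolar plane, which a
  cost alone can barely distinguish under pixel noise.
* **Normal agreement** — the real branch per marker is the branch pair
  whose plane normals agree between the views (tolerance 0.2 rad, with a
  closest-normal fallback for near-fronto markers where both branches
  nearly coincide anyway).

The per-pair cost cap is 4 mm and leaving a marker unmatched costs the
same, so a pairing is made only when it is cheaper than dropping both
partners.  An ambiguity error is raised only for the genuinely
unresolvable case of two same-view markers closer than 0.5 mm along one
epipolar line.  Matched rays are triangulated as the midpoint of the
common perpendicular; the gap is reported and grows monotonically with
injected noise.

## Kinematics and statistics

Rigid motion between marker plates is the cross-covariance SVD (Kabsch)
fit with determinant correction (via `scipy` `Rotation.align_vectors`),
requiring ≥3 non-collinear correspondences.  Rotations are reported as
the attitude vector n̄·α (α = arccos((tr R − 1)/2) in degrees; axis from
the skew part, switching to the eigenvector branch within 1e-6 rad of
180° where the sign is intrinsically ambiguous), orthogonally decomposed
onto the object axes as signed projections — their norm equals |α| for
orthonormal axes.  Accuracy is the mean and median of measured − 
reference; precision is the sample SD (divisor n−1) or, for repeated
measurements, the pooled RMS deviation with the biased 1/(l·m·n) divisor
exactly as defined (algebraically the pooled biased per-condition SD,
asserted numerically in the tests).

## Synthetic generator: what it does and does not emulate

Defaults reproduce the study apparatus: 1600×1200 cameras, axes crossing
at 40° on a target 300 mm away, 90° roll, a ø5 mm four-circle fiducial
in the plane z = 0, an 8×8 grid of ø2 mm circles at 10 mm pitch on a
plate at (0, −57, 10) mm, two four-circle square plates (15 mm side) for
the displacement protocols, camera-retreat steps of 10 mm, plate tilts
±15/30/45/60°, rotation steps of 2.25° over ±45°, translations of
0.5/1/5 mm with five repeats.  The principal distance (3400 px at 4 µm
pitch; a 2 mm marker spans ~23 px) and the plate/target offsets are the
package's own choices, fixed once so that every protocol scene keeps all
circles inside both frames without image-space overlap between grid and
fiducial.

Raster mode draws exact filled ellipses with 8× box-filter supersampling
at 8-bit depth; marching squares on such images carries an intrinsic
~0.05 px edge jitter from discretization, and Gaussian intensity noise
of σ = 5 counts keeps the total edge noise at that scale (σ = 10 roughly
doubles it; beyond σ ≈ 15 Otsu thresholding starts to fail).  The noise
model is i.i.d. per pixel (raster) or per ellipse centre (analytic),
plus an optional linear illumination gradient.

**Not emulated:** camera-calibration residuals, zoom/focus repositioning
error, lens distortion (supported by the model, off by default),
printing and mounting tolerances of the physical plates, tissue
backgrounds, blooming, or temporal effects.  Consequently the noise-free
synthetic protocols recover references at numerical precision (~1e-13),
and even the noisy raster protocols sit one to two orders of magnitude
below the accuracy and precision levels achievable with physical
hardware.  Passing tests demonstrate the correctness of the geometry and
estimation chain, not the field performance of any camera rig.

## Numerical notes

* Cone eigen-decomposition uses `eigh` on the symmetrized quadric; the
  sign is normalized to two positive eigenvalues and the axis oriented
  towards the scene.  An image conic without the (+,+,−) signature is
  rejected as an impossible viewing geometry.
* Ellipse fits run on centred, unit-RMS-scaled coordinates and are
  mapped back; orientation is reported for the major axis in [0, π).
* `gamma_from_ellipse` accepts d = ∞ for the orthographic limit
  (cos γ = a/b).
* Degenerate inputs raise typed errors (`errors.py`): behind-camera
  projections, non-ellipse conics, missing fiducial circles, parallel
  diagonals, k ≈ 0, |S/k| > 1, pose ties, near-parallel triangulation
  rays, ambiguous matches, collinear rigid fits, single-repeat
  precision.
* Rotation-matrix validation tolerates 1e-8 orthonormality error so that
  estimated (not re-orthogonalized) rotations pass through unchanged;
  the estimation itself is exact to ~1e-15 by construction.
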