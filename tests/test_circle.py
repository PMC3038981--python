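"""Eccentricity correction: cone alignment, tilt relation, interpretations.

The ground truth throughout is the forward model: place a 3D circle with
known centre and normal, project it exactly, and require the inverse
construction to recover the centre ray and normal.  The brute-force
oracle samples thousands of points on the 3D circle, projects them with
the plain pinhole projection and fits a conic — fully independent of the
closed-form conic used elsewhere.
"""

import numpy as np
import pytest

from circstereo import (
    align_cone,
    fit_ellipse,
    gamma_from_ellipse,
    interpret_circle,
    project,
    project_circle_exact,
)
from circstereo.camera import CameraIntrinsics



@pytest.fixture(scope="module")
def cam():
    return CameraIntrinsics(principal_point=np.array([799.5, 599.5]),
                            principal_distance=3400.0, pixel_pitch=0.004,
                            image_size=(1600, 1200))


def _random_circle(rng, cam, max_tilt_deg=60.0):
    """A circle inside the frustum, tilted up to max_tilt from fronto."""
    z = rng.uniform(200, 400)
    x = rng.uniform(-0.1, 0.1) * z
    y = rng.uniform(-0.1, 0.1) * z
    tilt = np.deg2rad(rng.uniform(0, max_tilt_deg))
    az = rng.uniform(0, 2 * np.pi)
    normal = np.array([np.sin(tilt) * np.cos(az),
                       np.sin(tilt) * np.sin(az), -np.cos(tilt)])
    return np.array([x, y, z]), normal, rng.uniform(0.5, 2.5)


def _brute_force_ellipse(centre, normal, radius, cam, n=3600):
    """Sampled-projection oracle: project n circle points, fit the conic."""
    n_vec = normal / np.linalg.norm(normal)
    t = np.array([1.0, 0, 0]) if abs(n_vec[0]) < 0.9 else np.array([0, 1.0, 0])
    u = np.cross(n_vec, t)
    u /= np.linalg.norm(u)
    v = np.cross(n_vec, u)
    th = np.linspace(0, 2 * np.pi, n, endpoint=False)
    pts3 = centre + radius * (np.outer(np.cos(th), u) + np.outer(np.sin(th), v))
    return fit_ellipse(project(pts3, cam))


class TestAlignCone:
    def test_centred_circle_already_aligned(self, cam):
        e, _ = project_circle_exact([0, 0, 300.0], [0, 0, -1.0], 1.0, cam)
        cone = align_cone(e, cam)
        assert abs(cone.semi_minor - cone.semi_major) < 1e-9
        # bisecting line of the aligned cone is the image Z-axis
        assert np.allclose(cone.rotation_to_axis @ np.array([0, 0, 1.0]),
                           [0, 0, 1.0], atol=1e-9)

    def test_aligned_axis_is_z_for_any_input(self, cam, rng):
        for _ in range(20):
            c, n, r = _random_circle(rng, cam)
            e, _ = project_circle_exact(c, n, r, cam)
            cone = align_cone(e, cam)
            # the cone axis eigenvector maps to z in the aligned frame
            w = cone.eigenvalues
            assert w[0] >= w[1] > 0 > w[2]

    def test_off_centre_fronto_circle_flattens(self, cam):
        """An off-axis circle parallel to the image plane subtends an
        oblique cone whose aligned section is an ellipse (a < b);
        verified against a numerically rotated point cone."""
        c = np.array([40.0, 25.0, 300.0])
        e, _ = project_circle_exact(c, [0, 0, -1.0], 2.0, cam)
        cone = align_cone(e, cam)
        assert cone.semi_minor < cone.semi_major
        # brute force: rotate sampled cone rays into the aligned frame and
        # intersect with the plane z = d; must land on the aligned ellipse
        oracle = _brute_force_ellipse(c, np.array([0, 0, -1.0]), 2.0, cam)
        d = cam.d_mm
        th = np.linspace(0, 2 * np.pi, 360, endpoint=False)
        # rays through the oracle ellipse (metric), rotated by the alignment
        centre_mm = cam.pixel_to_metric(oracle.centre)
        u = np.array([np.cos(oracle.orientation), np.sin(oracle.orientation)])
        v = np.array([-u[1], u[0]])
        pts = (centre_mm
               + np.outer(oracle.semi_major * cam.pixel_pitch * np.cos(th), u)
               + np.outer(oracle.semi_minor * cam.pixel_pitch * np.sin(th), v))
        rays = np.column_stack([pts, np.full(len(pts), d)])
        rot = cone.rotation_to_axis @ rays.T
        sect = d * rot[:2] / rot[2]
        val = (sect[0] / cone.semi_minor) ** 2 + (sect[1] / cone.semi_major) ** 2
        assert np.allclose(val, 1.0, atol=1e-6)


class TestGammaFromEllipse:
    def test_circle_is_parallel(self):
        g1, g2 = gamma_from_ellipse(3.0, 3.0, 15.0)
        assert g1 == 0.0 and g2 == 0.0

    def test_orthographic_limit_cosine(self):
        g, _ = gamma_from_ellipse(0.5, 1.0, np.inf)
        assert abs(np.degrees(g) - 60.0) < 1e-12

    def test_slimness_criterion_maps_to_limit_angle(self):
        """Axes ratio 0.2 corresponds to a marker-plane tilt of ~78.5 deg."""
        g, _ = gamma_from_ellipse(0.2, 1.0, np.inf)
        assert round(np.degrees(g), 1) == 78.5

    def test_argument_order_enforced(self):
        with pytest.raises(ValueError):
            gamma_from_ellipse(2.0, 1.0, 15.0)

    def test_monotone_decreasing_in_ratio(self):
        ratios = np.linspace(0.05, 1.0, 40)
        gammas = [gamma_from_ellipse(r, 1.0, 15.0)[0] for r in ratios]
        assert np.all(np.diff(gammas) < 0)

    def test_matches_pointwise_cone_oracle(self, cam, rng):
        """Eq.-1-style tilt must agree with the sampled-projection cone."""
        for _ in range(20):
            c, n, r = _random_circle(rng, cam, max_tilt_deg=55)
            e, _ = project_circle_exact(c, n, r, cam)
            cone = align_cone(e, cam)
            g, _ = gamma_from_ellipse(cone.semi_minor * cam.pixel_pitch * 0 +
                                      cone.semi_minor, cone.semi_major,
                                      cam.d_mm)
            interps = interpret_circle(e, cam)
            assert abs(interps[0].gamma - g) < 1e-8


class TestInterpretCircle:
    def test_degenerate_fronto_centred(self, cam):
        e, true_px = project_circle_exact([0, 0, 300.0], [0, 0, -1.0], 1.0, cam)
        a, b = interpret_circle(e, cam)
        # both interpretations coincide; centre ray hits the ellipse centre
        assert np.allclose(a.centre_ray.direction, b.centre_ray.direction,
                           atol=1e-9)
        assert a.centre_shift_px < 1e-9

    def test_real_branch_recovers_forward_truth(self, cam, rng):
        for _ in range(200):
            c, n, r = _random_circle(rng, cam)
            e, _ = project_circle_exact(c, n, r, cam)
            interps = interpret_circle(e, cam)
            best = min(interps, key=lambda it: np.linalg.norm(
                it.centre_at_radius(r) - c))
            assert np.linalg.norm(best.centre_at_radius(r) - c) < 1e-6
            assert min(np.linalg.norm(best.normal - n),
                       np.linalg.norm(best.normal + n)) < 1e-6

    def test_imaginary_branch_differs(self, cam):
        """Only one interpretation reproduces the true circle.  The two
        centres sit close together (thin-cone geometry), so the decisive
        discriminator is the plane normal — exactly why disambiguation
        goes through coplanarity or the second view."""
        c, r = np.array([20.0, -10.0, 300.0]), 1.0
        n = np.array([np.sin(0.6), 0.1, -np.cos(0.6)])
        n /= np.linalg.norm(n)
        e, _ = project_circle_exact(c, n, r, cam)
        interps = sorted(interpret_circle(e, cam),
                         key=lambda it: np.linalg.norm(it.centre_at_radius(r) - c))
        errs = [np.linalg.norm(it.centre_at_radius(r) - c) for it in interps]
        assert errs[0] < 1e-6 and errs[1] > 100 * max(errs[0], 1e-9)
        ang = np.degrees(np.arccos(abs(np.clip(interps[1].normal @ n, -1, 1))))
        assert ang > 1.0  # imaginary normal points elsewhere

    def test_eccentricity_is_real_and_correction_helps(self, cam):
        """2 mm circle tilted 45 deg at 300 mm: the ellipse centre and the
        corrected centre differ, and the corrected ray cuts the 3D centre
        error by far more than 10x."""
        c = np.array([30.0, 20.0, 300.0])
        n = np.array([np.sin(np.pi / 4), 0.0, -np.cos(np.pi / 4)])
        e, true_px = project_circle_exact(c, n, 1.0, cam)
        assert np.linalg.norm(e.centre - true_px) > 1e-3  # nonzero shift (px)
        interps = interpret_circle(e, cam)
        best = min(interps, key=lambda it: np.linalg.norm(
            it.centre_at_radius(1.0) - c))
        from circstereo import backproject_ray
        raw_ray = backproject_ray(e.centre, cam)
        corrected_abs = np.linalg.norm(
            c - best.centre_ray.direction * (best.centre_ray.direction @ c))
        raw_abs = np.linalg.norm(
            c - raw_ray.direction * (raw_ray.direction @ c))
        assert raw_abs / max(corrected_abs, 1e-12) > 10

    def test_reprojection_identity(self, cam, rng):
        """Each interpretation is a genuine 3D circle whose exact forward
        projection reproduces the observed ellipse."""
        for _ in range(20):
            c, n, r = _random_circle(rng, cam)
            e, _ = project_circle_exact(c, n, r, cam)
            for it in interpret_circle(e, cam):
                e2, _ = project_circle_exact(it.centre_at_radius(r),
                                             it.normal, r, cam)
                assert np.allclose(e2.centre, e.centre, atol=1e-6)
                assert abs(e2.semi_minor - e.semi_minor) < 1e-6
                assert abs(e2.semi_major - e.semi_major) < 1e-6

    def test_oracle_equivalence_brute_force(self, cam, rng):
        """Sampled-projection oracle: fit a conic to 3600 projected circle
        points, interpret it, and compare with projecting the known 3D
        centre directly."""
        for _ in range(20):
            c, n, r = _random_circle(rng, cam, max_tilt_deg=55)
            e = _brute_force_ellipse(c, n, r, cam)
            true_px = project(c, cam)
            interps = interpret_circle(e, cam)
            best = min(interps, key=lambda it: np.linalg.norm(
                it.centre_at_radius(r) - c))
            proj = project(best.centre_at_radius(r), cam)
            assert np.linalg.norm(proj - true_px) < 1e-5


class TestTwoViewDisambiguation:
    def test_real_normals_coincide_imaginary_do_not(self):
        """Seen from two viewpoints, the real circle normals agree while
        the imaginary ones diverge (the stereo disambiguation rule)."""
        from circstereo import RigConfig
        from circstereo.synthetic import SceneCircle, Scene, render

        rig = RigConfig()
        circ = SceneCircle(marker_id="m", centre=[5.0, -30.0, 12.0],
                           normal=[np.sin(0.3), 0.1, np.cos(0.3)],
                           radius=1.0)
        scene = Scene(scene_id="s", circles=(circ,))
        views = render(scene, rig)
        normals = []
        for v, pose, intr in zip(views, rig.camera_poses(), rig.intrinsics):
            interps = interpret_circle(v.ellipses[0], intr)
            true_n = pose.rotation @ circ.normal
            pair = sorted(interps, key=lambda it: min(
                np.linalg.norm(it.normal - true_n),
                np.linalg.norm(it.normal + true_n)))
            Rt = pose.rotation.T
            normals.append([Rt @ pair[0].normal, Rt @ pair[1].normal])

        def angle(u, v):
            return np.degrees(np.arccos(np.clip(abs(u @ v), -1, 1)))

        assert angle(normals[0][0], normals[1][0]) < 1e-5  # real branch
        assert angle(normals[0][1], normals[1][1]) > 1.0   # imaginary branch
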