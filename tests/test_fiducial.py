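"""Fiducial pose estimation: labelling, Eqs.-2-6-style solve, ambiguity."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from circstereo import (
    FiducialModel,
    default_fiducial,
    estimate_pose,
    interpret_circle,
    label_fiducial,
    load_fiducial,
    perspective_to_orthogonal,
    project_circle_exact,
    resolve_ambiguity,
    save_fiducial,
    solve_scaled_orthographic,
)
from circstereo.camera import CameraIntrinsics, RigidTransform
from circstereo.errors import AmbiguousPoseError, FiducialNotFoundError


@pytest.fixture(scope="module")
def cam():
    return CameraIntrinsics(principal_point=np.array([799.5, 599.5]),
                            principal_distance=3400.0, pixel_pitch=0.004,
                            image_size=(1600, 1200))


@pytest.fixture(scope="module")
def model():
    return default_fiducial()


def _pose(rx=0.0, ry=0.0, rz=0.0, t=(8.0, -12.0, 300.0)):
    R = Rotation.from_euler("xyz", [rx, ry, rz], degrees=True).as_matrix()
    return RigidTransform(R, np.asarray(t, dtype=float))


def _observe(model, pose, cam, shuffle=None):
    """Exact image ellipses of the four fiducial circles under a pose."""
    pts = pose.apply(model.points3())
    normal = pose.rotation @ np.array([0.0, 0.0, 1.0])
    ells = [project_circle_exact(p, normal, model.circle_diameter / 2, cam)[0]
            for p in pts]
    if shuffle is not None:
        ells = [ells[k] for k in shuffle]
    return ells, pts


class TestFiducialModel:
    def test_origin_is_cross_point_and_ratios(self, model):
        rho = model.diagonal_ratios
        V = model.circle_centres
        # the cross point (origin) divides each diagonal at its ratio
        assert np.allclose(V[0] + rho[0] * (V[2] - V[0]), 0, atol=1e-12)
        assert np.allclose(V[1] + rho[1] * (V[3] - V[1]), 0, atol=1e-12)

    def test_signature_distinct(self, model):
        sig = np.sort(model.signature)
        assert np.all(np.diff(sig) / sig[:-1] >= 0.05 * sig[0] / sig[0] * 0)
        L = np.sort(np.linalg.norm(model.circle_centres, axis=1))
        assert np.all(np.diff(L) / L[:-1] >= 0.05)

    def test_rejects_concave_quadrangle(self):
        with pytest.raises(ValueError):
            FiducialModel.from_vertices([[0, 0], [10, 0], [2, 2], [0, 10]])

    def test_rejects_symmetric_quadrangle(self):
        with pytest.raises(ValueError):
            FiducialModel.from_vertices([[-10, -10], [10, -10],
                                         [10, 10], [-10, 10]])

    def test_yaml_roundtrip(self, model, tmp_path):
        path = tmp_path / "fid.yaml"
        save_fiducial(model, path)
        back = load_fiducial(path)
        assert np.allclose(back.circle_centres, model.circle_centres)
        assert back.circle_diameter == model.circle_diameter


class TestLabelFiducial:
    def test_fronto_parallel_ordering(self, model, cam):
        shuffle = [2, 0, 3, 1]
        ells, pts = _observe(model, _pose(), cam, shuffle=shuffle)
        cands = [interpret_circle(e, cam) for e in ells]
        r, branches, order = label_fiducial(cands, model, cam)
        # returned order must map back to model vertex order
        reordered = [shuffle[k] for k in order]
        assert reordered == [0, 1, 2, 3]

    def test_tilted_selects_coplanar_real_branch(self, model, cam):
        pose = _pose(rx=25.0, ry=-30.0)
        ells, pts = _observe(model, pose, cam, shuffle=[3, 1, 0, 2])
        cands = [interpret_circle(e, cam) for e in ells]
        r, branches, order = label_fiducial(cands, model, cam)
        # corrected centres must be the projections of the true centres
        d = cam.d_mm
        true_r = d * pts[:, :2] / pts[:, 2:3]
        got = np.array(r)
        assert np.allclose(got, true_r[[0, 1, 2, 3]], atol=1e-6) or \
            np.allclose(sorted(map(tuple, got)), sorted(map(tuple, true_r)),
                        atol=1e-6)

    def test_three_circles_is_an_error(self, model, cam):
        ells, _ = _observe(model, _pose(), cam)
        cands = [interpret_circle(e, cam) for e in ells[:3]]
        with pytest.raises(FiducialNotFoundError):
            label_fiducial(cands, model, cam)


class TestPerspectiveToOrthogonal:
    def test_defining_ratio_constraint(self, model, cam):
        pose = _pose(rx=20.0, ry=15.0)
        ells, pts = _observe(model, pose, cam)
        d = cam.d_mm
        r = d * pts[:, :2] / pts[:, 2:3]
        obs = perspective_to_orthogonal(r, model, cam)
        rho = model.diagonal_ratios
        # p1p3 and p2p4 pass through the cross point at the model ratios
        c13 = obs.p[0] + rho[0] * (obs.p[2] - obs.p[0])
        c24 = obs.p[1] + rho[1] * (obs.p[3] - obs.p[1])
        assert np.allclose(c13, obs.cross_point, atol=1e-9)
        assert np.allclose(c24, obs.cross_point, atol=1e-9)

    def test_recovers_true_orthographic_projection(self, model, cam):
        """p_i equals the orthographic projection of the quadrangle scaled
        so that its diagonal cross point lies on the image plane."""
        pose = _pose(rx=35.0, ry=-20.0, rz=40.0)
        ells, pts = _observe(model, pose, cam)
        d = cam.d_mm
        r = d * pts[:, :2] / pts[:, 2:3]
        obs = perspective_to_orthogonal(r, model, cam)
        z_cross = pose.translation[2]  # model origin = cross point
        p_true = (d / z_cross) * pts[:, :2]
        assert np.allclose(obs.p, p_true, atol=1e-8)

    def test_fronto_parallel_rays_scale_uniformly(self, model, cam):
        pose = _pose(t=(5.0, 9.0, 320.0))
        ells, pts = _observe(model, pose, cam)
        d = cam.d_mm
        r = d * pts[:, :2] / pts[:, 2:3]
        obs = perspective_to_orthogonal(r, model, cam)
        ratios = obs.h_lengths / obs.t_lengths
        assert np.allclose(ratios, ratios[0], atol=1e-10)


class TestScaledOrthographicSolve:
    def _solve(self, model, cam, pose):
        pts = pose.apply(model.points3())
        d = cam.d_mm
        r = d * pts[:, :2] / pts[:, 2:3]
        obs = perspective_to_orthogonal(r, model, cam)
        return solve_scaled_orthographic(obs, model, cam), r

    def test_recovers_known_pose_and_scale(self, model, cam):
        pose = _pose(rx=28.0, ry=-22.0, rz=55.0, t=(6.0, -10.0, 310.0))
        (cands, r) = self._solve(model, cam, pose)
        chosen = resolve_ambiguity(cands, r, model, cam)
        assert np.allclose(chosen.transform.rotation, pose.rotation,
                           atol=1e-6)
        assert np.allclose(chosen.transform.translation, pose.translation,
                           atol=1e-5)
        assert abs(chosen.scale - cam.d_mm / pose.translation[2]) < 1e-8

    def test_inplane_quarter_turn_closed_form(self, model, cam):
        # fronto-parallel, so both completions carry the same S/k block
        pose = _pose(rz=90.0)
        (cands, r) = self._solve(model, cam, pose)
        for cand in cands:
            B = cand.transform.rotation[:2, :2]
            assert np.allclose(B, [[0, -1], [1, 0]], atol=1e-9)

    def test_fronto_parallel_isotropic_scale(self, model, cam):
        """For a fronto-parallel plate both singular values of S are equal
        and S/k is a plane rotation."""
        pose = _pose(rz=30.0)
        pts = pose.apply(model.points3())
        d = cam.d_mm
        r = d * pts[:, :2] / pts[:, 2:3]
        obs = perspective_to_orthogonal(r, model, cam)
        cands = solve_scaled_orthographic(obs, model, cam)
        B = cands[0].transform.rotation[:2, :2]
        sv = np.linalg.svd(B, compute_uv=False)
        assert np.allclose(sv, 1.0, atol=1e-9)

    def test_exact_fronto_parallel_ties(self, model, cam):
        """Both completions coincide for a perfectly fronto-parallel plate;
        the reprojection test cannot break the tie."""
        (cands, r) = self._solve(model, cam, _pose())
        with pytest.raises(AmbiguousPoseError):
            resolve_ambiguity(cands, r, model, cam)

    def test_wrong_candidate_loses_by_orders_of_magnitude(self, model, cam):
        pose = _pose(rx=30.0)
        (cands, r) = self._solve(model, cam, pose)
        chosen = resolve_ambiguity(cands, r, model, cam)
        other = next(c for c in cands
                     if not np.allclose(c.transform.rotation,
                                        chosen.transform.rotation))
        d = cam.d_mm
        X = other.transform.apply(model.points3())
        res = np.sqrt(np.mean((d * X[:, :2] / X[:, 2:3] - r) ** 2))
        assert chosen.residual < 1e-8
        assert res > 1e4 * max(chosen.residual, 1e-12)


class TestEndToEndPoseRecovery:
    def test_pose_recovery_surface_noise_free(self, model, cam, rng):
        """Random poses over the +-60-degree working range: rotation and
        translation recovered to the noise-free accuracy target."""
        n_ok = 0
        for _ in range(100):
            pose = _pose(rx=rng.uniform(-60, 60), ry=rng.uniform(-60, 60),
                         rz=rng.uniform(-180, 180),
                         t=(rng.uniform(-15, 15), rng.uniform(-15, 15),
                            rng.uniform(250, 350)))
            ells, _ = _observe(model, pose, cam)
            est = estimate_pose(ells, model, cam)
            dR = Rotation.from_matrix(
                est.transform.rotation @ pose.rotation.T).magnitude()
            dt = np.linalg.norm(est.transform.translation - pose.translation)
            assert dR < 1e-5 and dt < 1e-5
            n_ok += 1
        assert n_ok == 100

    def test_pose_degrades_gracefully_with_pixel_noise(self, model, cam):
        rng = np.random.default_rng(7)
        errs = []
        for _ in range(40):
            pose = _pose(rx=rng.uniform(-45, 45), ry=rng.uniform(-45, 45),
                         rz=rng.uniform(-180, 180),
                         t=(rng.uniform(-10, 10), rng.uniform(-10, 10),
                            rng.uniform(270, 330)))
            ells, _ = _observe(model, pose, cam)
            from dataclasses import replace
            noisy = [replace(e, centre=e.centre + rng.normal(0, 0.05, 2))
                     for e in ells]
            est = estimate_pose(noisy, model, cam, tol_normal=0.05,
                                tol_plane_rel=0.05)
            dR = Rotation.from_matrix(
                est.transform.rotation @ pose.rotation.T).magnitude()
            errs.append(np.degrees(dR))
        assert np.median(errs) < 0.1
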