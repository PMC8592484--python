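import json

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pushtrack.geometry import (
    BehindCameraError,
    CalibrationSchemaError,
    CameraModel,
    DegenerateConfigurationError,
    DegenerateProjectionError,
    InsufficientViewsError,
    calibration_from_dict,
    calibration_to_dict,
    estimate_rigid_alignment,
    load_calibration,
    look_at_camera,
    project_point,
    project_points,
    save_calibration,
    triangulate_point,
    wand_accuracy,
)
from pushtrack.geometry import CalibrationSet


def _random_rotation(rng):
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
        [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
        [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
    ])


class TestProjection:
    def test_optical_axis_point_maps_to_principal_point(self):
        cam = look_at_camera("c", np.array([0.0, -5.0, 1.0]),
                             np.array([0.0, 0.0, 1.0]), 480.0, (960, 540))
        uv = project_point(cam, np.array([0.0, 0.0, 1.0]))
        assert np.allclose(uv, cam.intrinsic_matrix[:2, 2], atol=1e-9)

    def test_matches_homogeneous_multiply_oracle(self, quad_cameras):
        rng = np.random.default_rng(11)
        cam = quad_cameras[1]
        P = cam.projection_matrix
        for _ in range(25):
            X = rng.uniform([-2, -2, 0], [3, 3, 2])
            h = P @ np.append(X, 1.0)
            expected = h[:2] / h[2]
            assert np.allclose(project_point(cam, X), expected, atol=1e-9)

    def test_camera_centre_is_degenerate(self, quad_cameras):
        cam = quad_cameras[0]
        with pytest.raises(DegenerateProjectionError):
            project_point(cam, cam.centre)

    def test_behind_camera_is_flagged_not_projected(self, quad_cameras):
        cam = quad_cameras[0]
        behind = cam.centre + cam.rotation.T @ np.array([0.0, 0.0, -1.0])
        with pytest.raises(BehindCameraError):
            project_point(cam, behind)
        _, in_front = project_points(cam, behind[None, :])
        assert not in_front[0]

    def test_distortion_roundtrip(self):
        cam = CameraModel(
            camera_id="d",
            intrinsic_matrix=np.array([[500.0, 0, 320], [0, 500, 240], [0, 0, 1]]),
            distortion=np.array([-0.2, 0.05, 1e-3, -1e-3, 0.0]),
            rotation=np.eye(3),
            translation=np.zeros(3),
            image_size=(640, 480),
        )
        from pushtrack.geometry import undistort_pixel

        pt = np.array([0.3, -0.2, 2.0])
        uv = project_point(cam, pt)
        xn = undistort_pixel(cam, uv)[0]
        assert np.allclose(xn, pt[:2] / pt[2], atol=1e-9)


class TestTriangulation:
    def test_noiseless_recovery(self, quad_cameras):
        X = np.array([1.0, 0.2, 0.9])
        obs = [(c, project_point(c, X)) for c in quad_cameras]
        res = triangulate_point(obs)
        assert np.linalg.norm(res.point - X) < 1e-6
        assert res.rms_residual_px < 1e-6

    def test_single_camera_insufficient(self, quad_cameras):
        cam = quad_cameras[0]
        with pytest.raises(InsufficientViewsError):
            triangulate_point([(cam, np.array([100.0, 100.0]))])
        with pytest.raises(InsufficientViewsError):
            triangulate_point([(cam, np.array([100.0, 100.0])),
                               (cam, np.array([101.0, 100.0]))])

    def test_noisy_monte_carlo_accuracy(self):
        """0.5 px noise, 9 full-HD cameras, points ~5 m away: < 5 mm error."""
        from pushtrack.synthetic import make_camera_ring

        rng = np.random.default_rng(42)
        cams = list(make_camera_ring(image_size=(1920, 1080)))
        errs = []
        for _ in range(100):
            X = rng.uniform([4, -0.5, 0.1], [6, 0.5, 1.8])
            obs = []
            for c in cams:
                uv = project_point(c, X) + rng.normal(0, 0.5, 2)
                obs.append((c, uv))
            res = triangulate_point(obs)
            errs.append(np.linalg.norm(res.point - X))
        assert np.mean(errs) < 5e-3

    @settings(deadline=None, max_examples=20, derandomize=True)
    @given(st.tuples(st.floats(0.5, 9.0), st.floats(-0.8, 0.8),
                     st.floats(0.05, 1.9)))
    def test_roundtrip_reprojection_property(self, point):
        """Triangulating noiseless views then reprojecting reproduces them."""
        from pushtrack.synthetic import make_camera_ring

        cams = list(make_camera_ring(n=4, image_size=(480, 270)))
        X = np.array(point)
        obs = [(c, project_point(c, X)) for c in cams]
        res = triangulate_point(obs)
        for c, uv in obs:
            assert np.allclose(project_point(c, res.point), uv, atol=1e-6)


class TestRigidAlignment:
    def test_identity(self):
        pts = np.random.default_rng(0).normal(size=(10, 3))
        al = estimate_rigid_alignment(pts, pts)
        assert np.allclose(al.rotation, np.eye(3), atol=1e-12)
        assert np.allclose(al.translation, 0.0, atol=1e-12)
        assert al.rms_residual < 1e-12

    @pytest.mark.parametrize("seed", [1, 2, 3, 4])
    def test_recovers_generating_transform(self, seed):
        rng = np.random.default_rng(seed)
        R0 = _random_rotation(rng)
        t0 = rng.normal(size=3)
        a = rng.normal(size=(8, 3))
        b = a @ R0.T + t0
        al = estimate_rigid_alignment(a, b)
        assert np.allclose(al.rotation, R0, atol=1e-9)
        assert np.allclose(al.translation, t0, atol=1e-9)
        assert al.rms_residual < 1e-9

    def test_collinear_degenerate(self):
        a = np.outer(np.arange(5.0), np.array([1.0, 2.0, 3.0]))
        with pytest.raises(DegenerateConfigurationError):
            estimate_rigid_alignment(a, a + 1.0)
        with pytest.raises(DegenerateConfigurationError):
            estimate_rigid_alignment(a[:2], a[:2])

    def test_residual_invariant_to_relabelling(self):
        rng = np.random.default_rng(5)
        a = rng.normal(size=(12, 3))
        b = a @ _random_rotation(rng).T + 0.3 * rng.normal(size=(12, 3))
        r1 = estimate_rigid_alignment(a, b).rms_residual
        perm = rng.permutation(12)
        r2 = estimate_rigid_alignment(a[perm], b[perm]).rms_residual
        assert np.isclose(r1, r2, atol=1e-12)

    def test_scale_variant_recovers_scale(self):
        rng = np.random.default_rng(6)
        a = rng.normal(size=(9, 3))
        b = 1.7 * (a @ _random_rotation(rng).T) + 2.0
        al = estimate_rigid_alignment(a, b, allow_scale=True)
        assert np.isclose(al.scale, 1.7, atol=1e-9)
        assert al.rms_residual < 1e-9


class TestWandAccuracy:
    def test_constant_endpoints(self):
        pts = np.zeros((10, 2, 3))
        pts[:, 1, 0] = 0.5
        mean, sd = wand_accuracy(pts, 0.5)
        assert mean == pytest.approx(0.5)
        assert sd == 0.0

    def test_sample_sd_convention(self):
        pts = np.zeros((2, 2, 3))
        pts[0, 1, 0] = 0.499
        pts[1, 1, 0] = 0.501
        mean, sd = wand_accuracy(pts)
        assert mean == pytest.approx(0.5)
        assert sd == pytest.approx(np.std([0.499, 0.501], ddof=1))

    def test_triangulated_wand_end_to_end(self, quad_cameras):
        rng = np.random.default_rng(9)
        frames = []
        for _ in range(15):
            p1 = rng.uniform([-1, -1, 0.2], [1, 1, 1.5])
            direction = rng.normal(size=3)
            direction /= np.linalg.norm(direction)
            p2 = p1 + 0.5 * direction
            ends = []
            for p in (p1, p2):
                obs = [(c, project_point(c, p)) for c in quad_cameras]
                ends.append(triangulate_point(obs).point)
            frames.append(ends)
        mean, _ = wand_accuracy(np.asarray(frames), 0.5)
        assert abs(mean - 0.5) < 1e-6

    def test_empty_series_rejected(self):
        with pytest.raises(ValueError):
            wand_accuracy(np.zeros((0, 2, 3)))


class TestCalibrationIO:
    def test_roundtrip(self, tmp_path, quad_cameras):
        calib = CalibrationSet(cameras=tuple(quad_cameras))
        path = tmp_path / "calibration.json"
        save_calibration(calib, path)
        loaded = load_calibration(path)
        for a, b in zip(calib, loaded):
            assert a.camera_id == b.camera_id
            assert np.allclose(a.projection_matrix, b.projection_matrix)

    def test_schema_error_names_offending_field(self, tmp_path, quad_cameras):
        doc = calibration_to_dict(CalibrationSet(cameras=tuple(quad_cameras)))
        del doc["cameras"][1]["rotation"]
        with pytest.raises(CalibrationSchemaError, match=r"cameras\[1\].*rotation"):
            calibration_from_dict(doc)

    def test_invalid_rotation_rejected(self, quad_cameras):
        doc = calibration_to_dict(CalibrationSet(cameras=tuple(quad_cameras)))
        doc["cameras"][0]["rotation"] = (2 * np.eye(3)).tolist()
        with pytest.raises(CalibrationSchemaError):
            calibration_from_dict(doc)
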