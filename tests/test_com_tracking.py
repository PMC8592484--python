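import numpy as np
import pytest

from pushtrack.com_tracking import (
    Box2D,
    BodyBox3D,
    InsufficientDataError,
    KalmanConfig,
    SledModel,
    central_diff_velocity,
    com_from_boxes,
    fit_sled_pose,
    init_body_box_3d,
    kalman_smooth,
    optimise_body_box,
    part_boxes_2d,
)
from pushtrack.geometry import CalibrationSet, InsufficientViewsError, project_point
from pushtrack.masks import PART_CODES

FPS = 200.0


class TestPartBoxes:
    def test_tight_box_around_blob(self):
        img = np.zeros((200, 300), np.uint8)
        img[50:70, 100:110] = PART_CODES["torso"]
        box = part_boxes_2d(img, PART_CODES["torso"])
        assert (box.u0, box.v0, box.u1, box.v1) == (100, 50, 109, 69)

    def test_empty_mask_gives_none(self):
        assert part_boxes_2d(np.zeros((50, 50), np.uint8),
                             PART_CODES["torso"]) is None

    def test_two_blobs_larger_wins_with_flag(self):
        img = np.zeros((200, 300), np.uint8)
        img[20:60, 20:60] = PART_CODES["torso"]     # 1600 px
        img[100:135, 200:235] = PART_CODES["torso"]  # 1225 px: comparable
        box = part_boxes_2d(img, PART_CODES["torso"])
        assert (box.u0, box.v0) == (20, 20)
        assert box.ambiguous


class TestComFromBoxes:
    def test_coincident_centres(self):
        p = np.tile([1.0, 2.0, 3.0], (5, 1))
        ok = np.ones(5, bool)
        out, valid, _ = com_from_boxes(p, ok, p, ok, weights=(0.3, 0.7))
        assert np.allclose(out, p)
        assert valid.all()

    def test_hand_arithmetic_weighting(self):
        head = np.array([[0.0, 0.0, 1.7]])
        torso = np.array([[0.0, 0.0, 1.2]])
        ok = np.ones(1, bool)
        out, _, _ = com_from_boxes(head, ok, torso, ok)
        assert out[0, 2] == pytest.approx(0.14 * 1.7 + 0.86 * 1.2)  # 1.27

    def test_missing_head_falls_back_to_torso(self):
        head = np.full((1, 3), np.nan)
        torso = np.array([[1.0, 0.0, 1.2]])
        out, valid, partial = com_from_boxes(
            head, np.zeros(1, bool), torso, np.ones(1, bool))
        assert np.allclose(out[0], torso[0])
        assert valid[0] and partial[0]

    def test_both_missing_invalid(self):
        nanrow = np.full((1, 3), np.nan)
        out, valid, _ = com_from_boxes(nanrow, np.zeros(1, bool),
                                       nanrow, np.zeros(1, bool))
        assert not valid[0]

    def test_weights_must_sum_to_one(self):
        p = np.zeros((1, 3))
        with pytest.raises(ValueError):
            com_from_boxes(p, np.ones(1, bool), p, np.ones(1, bool), (0.5, 0.6))


def _project_box_2d(cam, box):
    corners = box.corners
    us, vs = [], []
    for c in corners:
        uv = project_point(cam, c)
        us.append(uv[0])
        vs.append(uv[1])
    return Box2D(u0=int(min(us)), v0=int(min(vs)), u1=int(max(us)),
                 v1=int(max(vs)))


class TestBodyBox3D:
    def test_init_and_optimise_recover_known_box(self, small_ring):
        truth = BodyBox3D(part="torso", centre=np.array([5.0, 0.1, 1.1]),
                          dimensions=np.array([0.35, 0.35, 0.55]))
        boxes = {c.camera_id: _project_box_2d(c, truth) for c in small_ring}
        init = init_body_box_3d(boxes, small_ring, "torso")
        assert np.linalg.norm(init.centre - truth.centre) < 0.05
        # perturb and re-optimise: the fit should pull it back
        init.centre = truth.centre + np.array([0.06, -0.04, 0.05])
        fitted = optimise_body_box(init, boxes, small_ring)
        assert fitted.valid
        assert np.linalg.norm(fitted.centre - truth.centre) < 0.05

    def test_perfect_initialisation_is_fixed_point(self, small_ring):
        truth = BodyBox3D(part="head", centre=np.array([4.0, -0.2, 1.6]),
                          dimensions=np.array([0.20, 0.20, 0.25]))
        boxes = {c.camera_id: _project_box_2d(c, truth) for c in small_ring}
        fitted = optimise_body_box(truth, boxes, small_ring)
        assert np.linalg.norm(fitted.centre - truth.centre) < 0.02

    def test_single_view_insufficient(self, small_ring):
        cam = list(small_ring)[0]
        with pytest.raises(InsufficientViewsError):
            init_body_box_3d({cam.camera_id: Box2D(10, 10, 20, 20)},
                             small_ring, "torso")

    def test_occupancy_peak_snaps_ground_position(self, small_ring):
        truth = BodyBox3D(part="torso", centre=np.array([5.0, 0.0, 1.1]),
                          dimensions=np.array([0.35, 0.35, 0.55]))
        boxes = {c.camera_id: _project_box_2d(c, truth) for c in small_ring}
        peaks = [np.array([7.5, 0.5]), np.array([5.02, 0.01])]
        init = init_body_box_3d(boxes, small_ring, "torso", body_peaks=peaks)
        assert np.allclose(init.centre[:2], [5.02, 0.01])


class TestSledPose:
    def _observe(self, calib, corners, conf=1.0, drop=()):
        obs = {}
        for cid_idx, corner in enumerate(corners):
            if cid_idx in drop:
                continue
            views = []
            for cam in calib:
                try:
                    uv = project_point(cam, corner)
                except Exception:
                    continue
                views.append((cam.camera_id, uv, conf))
            obs[cid_idx] = views
        return obs

    def test_noiseless_pose_recovery(self, small_ring):
        model = SledModel(template_corners=np.array(
            [[-0.45, -0.25, 0], [0.45, -0.25, 0], [0.45, 0.25, 0],
             [-0.45, 0.25, 0]]))
        theta = 0.2
        R = np.array([[np.cos(theta), -np.sin(theta), 0],
                      [np.sin(theta), np.cos(theta), 0], [0, 0, 1.0]])
        t = np.array([5.0, -0.6, 0.15])
        corners = model.template_corners @ R.T + t
        pose = fit_sled_pose(self._observe(small_ring, corners),
                             small_ring, model)
        assert pose is not None
        assert np.allclose(pose.rotation, R, atol=1e-6)
        assert np.allclose(pose.translation, t, atol=1e-6)
        assert np.allclose(pose.centroid, model.centroid @ R.T + t, atol=1e-6)

    def test_two_corners_underdetermined(self, small_ring):
        model = SledModel(template_corners=np.array(
            [[-0.45, -0.25, 0], [0.45, -0.25, 0], [0.45, 0.25, 0],
             [-0.45, 0.25, 0]]))
        corners = model.template_corners + np.array([5.0, 0.0, 0.15])
        obs = self._observe(small_ring, corners, drop=(0, 1))
        assert fit_sled_pose(obs, small_ring, model) is None

    def test_low_confidence_detection_gated(self, small_ring):
        model = SledModel(template_corners=np.array(
            [[-0.45, -0.25, 0], [0.45, -0.25, 0], [0.45, 0.25, 0],
             [-0.45, 0.25, 0]]))
        t = np.array([5.0, -0.6, 0.15])
        corners = model.template_corners + t
        obs = self._observe(small_ring, corners)
        # corner 3 grossly mislabelled but with low confidence: ignored
        bad = [(cid, uv + 300.0, 0.2) for cid, uv, _ in obs[3]]
        obs[3] = bad
        pose = fit_sled_pose(obs, small_ring, model)
        assert pose is not None
        assert pose.n_corners == 3
        assert np.allclose(pose.translation, t, atol=1e-6)


class TestKalman:
    def test_constant_velocity_is_reproduced_exactly(self):
        n = 60
        t = np.arange(n) / FPS
        z = np.stack([2 * t + 1, -3 * t, 0.5 + 0 * t], 1)
        pos, vel, ok = kalman_smooth(z, np.ones(n, bool), FPS)
        assert np.abs(pos - z).max() < 1e-6
        assert np.abs(vel - [2, -3, 0]).max() < 1e-6
        assert ok.all()

    def test_matches_batch_least_squares_line(self):
        """With q -> 0 and a diffuse prior the smoother is the OLS line fit."""
        rng = np.random.default_rng(0)
        n = 10
        t = np.arange(n) / FPS
        z = np.stack([5 * t + 0.3 + rng.normal(0, 0.02, n),
                      np.zeros(n), np.zeros(n)], 1)
        cfg = KalmanConfig(accel_spectral_density=1e-12, measurement_sd=0.02,
                           init_var=1e12)
        pos, _, _ = kalman_smooth(z, np.ones(n, bool), FPS, cfg)
        A = np.stack([np.ones(n), t], 1)
        coef, *_ = np.linalg.lstsq(A, z[:, 0], rcond=None)
        assert np.abs(pos[:, 0] - A @ coef).max() < 1e-6

    def test_noise_reduction(self):
        rng = np.random.default_rng(1)
        n = 200
        t = np.arange(n) / FPS
        clean = np.stack([6 * t, np.zeros(n), np.zeros(n)], 1)
        z = clean + rng.normal(0, 0.02, (n, 3))
        pos, _, _ = kalman_smooth(z, np.ones(n, bool), FPS)
        rmse_raw = np.sqrt(np.mean((z - clean) ** 2))
        rmse_smooth = np.sqrt(np.mean((pos - clean) ** 2))
        assert rmse_smooth < rmse_raw

    def test_metre_spike_is_gated(self):
        n = 80
        t = np.arange(n) / FPS
        z = np.stack([4 * t, np.zeros(n), np.zeros(n)], 1)
        z[40, 0] += 1.0
        pos, _, _ = kalman_smooth(z, np.ones(n, bool), FPS)
        assert abs(pos[40, 0] - 4 * t[40]) < 0.02

    def test_invalid_frames_bridged_by_prediction(self):
        n = 60
        t = np.arange(n) / FPS
        z = np.stack([3 * t, np.zeros(n), np.zeros(n)], 1)
        valid = np.ones(n, bool)
        valid[20:25] = False
        z[20:25] = np.nan
        pos, _, ok = kalman_smooth(z, valid, FPS)
        assert ok[20:25].all()
        assert np.abs(pos[20:25, 0] - 3 * t[20:25]).max() < 1e-6

    def test_insufficient_data(self):
        with pytest.raises(InsufficientDataError):
            kalman_smooth(np.zeros((5, 3)), np.array([1, 0, 0, 0, 0], bool), FPS)

    def test_shift_invariance(self):
        rng = np.random.default_rng(2)
        n = 100
        t = np.arange(n) / FPS
        z = np.stack([4 * t + rng.normal(0, 0.01, n), np.zeros(n),
                      np.zeros(n)], 1)
        v1 = kalman_smooth(z, np.ones(n, bool), FPS)[1]
        v2 = kalman_smooth(z + 7.0, np.ones(n, bool), FPS)[1]
        assert np.abs(v1 - v2).max() < 1e-9


class TestCentralDiff:
    def test_linear_exact(self):
        t = np.arange(20) / FPS
        p = np.stack([2 * t, np.zeros(20), np.zeros(20)], 1)
        v, one_sided = central_diff_velocity(p, FPS)
        assert np.allclose(v[:, 0], 2.0)
        assert one_sided[0] and one_sided[-1] and not one_sided[1:-1].any()

    def test_quadratic_exact_interior(self):
        t = np.arange(20) / FPS
        p = np.stack([t**2, np.zeros(20), np.zeros(20)], 1)
        v, _ = central_diff_velocity(p, FPS)
        assert np.allclose(v[1:-1, 0], 2 * t[1:-1])

    def test_random_walk_matches_index_arithmetic(self):
        rng = np.random.default_rng(3)
        p = rng.normal(size=(30, 3))
        v, _ = central_diff_velocity(p, FPS)
        i = 13
        assert np.allclose(v[i], (p[i + 1] - p[i - 1]) * FPS / 2)

    def test_too_short(self):
        with pytest.raises(InsufficientDataError):
            central_diff_velocity(np.zeros((2, 3)), FPS)
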