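"""Athlete mass-centre proxy and sled tracking, with Kalman smoothing.

The athlete CoM is proxied by 3D bounding boxes fitted to the head and
torso segmentations: per camera a tight 2D box is drawn around each
part, a 3D box is initialised from triangulation (cross-checked against
a body-height occupancy peak) and then optimised so its projections
overlap the 2D boxes; the CoM proxy is the mass-weighted average of the
two box centres.  The sled is a rigid template whose pose is solved by
Procrustes from triangulated corner detections.  Both centroid series
run through an outlier-gated forward Kalman filter with
Rauch-Tung-Striebel backward smoothing (the "bi-directional Kalman
filter"), and velocities come from finite central differences.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.stats import chi2

from .geometry import (
    CalibrationSet,
    DegenerateConfigurationError,
    GeometryError,
    InsufficientViewsError,
    estimate_rigid_alignment,
    triangulate_point,
)

PART_DIMENSIONS = {
    "torso": (0.35, 0.35, 0.55),
    "head": (0.20, 0.20, 0.25),
}
# rough expected pixel counts used to scale detection confidence
EXPECTED_PART_PIXELS = {"torso": 2000.0, "head": 300.0}


@dataclass
class Box2D:
    """Tight axis-aligned pixel box (inclusive corners) with confidence."""

    u0: int
    v0: int
    u1: int
    v1: int
    confidence: float = 1.0
    ambiguous: bool = False

    @property
    def centre(self) -> np.ndarray:
        return np.array([(self.u0 + self.u1) / 2.0, (self.v0 + self.v1) / 2.0])

    @property
    def area(self) -> int:
        return (self.u1 - self.u0 + 1) * (self.v1 - self.v0 + 1)


@dataclass
class BodyBox3D:
    part: str
    centre: np.ndarray
    dimensions: np.ndarray
    confidence: float = 1.0
    valid: bool = True

    def __post_init__(self):
        self.centre = np.asarray(self.centre, float)
        self.dimensions = np.asarray(self.dimensions, float)
        if np.any(self.dimensions <= 0):
            raise ValueError("box dimensions must be positive")

    @property
    def corners(self) -> np.ndarray:
        signs = np.array([[sx, sy, sz] for sx in (-1, 1) for sy in (-1, 1)
                          for sz in (-1, 1)], float)
        return self.centre + 0.5 * signs * self.dimensions


@dataclass
class SledModel:
    """Rigid sled: template corners in the sled frame, centroid at their mean."""

    template_corners: np.ndarray  # (4, 3) m

    def __post_init__(self):
        self.template_corners = np.asarray(self.template_corners, float)
        c = self.template_corners - self.template_corners.mean(axis=0)
        if np.linalg.svd(c, compute_uv=False)[1] < 1e-9:
            raise ValueError("template corners must not be collinear")

    @property
    def centroid(self) -> np.ndarray:
        return self.template_corners.mean(axis=0)


@dataclass
class SledPose:
    rotation: np.ndarray
    translation: np.ndarray
    centroid: np.ndarray
    rms_residual: float
    n_corners: int


@dataclass
class Trajectory:
    """Uniformly sampled 3D track with per-frame validity."""

    times: np.ndarray
    positions: np.ndarray
    velocities: np.ndarray
    valid: np.ndarray
    label: str = ""
    flags: dict = field(default_factory=dict)


@dataclass(frozen=True)
class KalmanConfig:
    """Constant-velocity, white-noise-acceleration process model.

    The acceleration spectral density default (5 (m/s^2)^2 s) tolerates
    sprint accelerations of ~10 m/s^2; measurement noise reflects a few
    centimetres of box-centre jitter; the gate is the chi-square 99th
    percentile for a 3-dof innovation.
    """

    accel_spectral_density: float = 5.0  # (m/s^2)^2 * s
    measurement_sd: float = 0.03         # m
    gate_quantile: float = 0.99
    init_var: float = 1e4

    def __post_init__(self):
        if min(self.accel_spectral_density, self.measurement_sd) <= 0:
            raise ValueError("noise parameters must be positive")


class InsufficientDataError(ValueError):
    pass


# ---------------------------------------------------------------------------
# 2D part boxes


def part_boxes_2d(labels: np.ndarray, part_code: int, part: str = "torso",
                  min_pixels: int = 20) -> Box2D | None:
    """Tight box around a part label; the larger blob wins if disjoint."""
    mask = labels == part_code
    count = int(mask.sum())
    if count < min_pixels:
        return None
    rows = np.flatnonzero(mask.any(axis=1))
    cols = np.flatnonzero(mask.any(axis=0))
    v0, v1 = int(rows[0]), int(rows[-1])
    u0, u1 = int(cols[0]), int(cols[-1])
    ambiguous = False
    # cheap disjointness probe: gaps in both marginal profiles
    if (np.diff(rows) > 1).any() and (np.diff(cols) > 1).any():
        sub = mask[v0:v1 + 1, u0:u1 + 1]
        lab, n = ndimage.label(sub)
        if n > 1:
            sizes = ndimage.sum_labels(sub, lab, index=np.arange(1, n + 1))
            main = int(np.argmax(sizes)) + 1
            if sizes.max() < 2 * np.sort(sizes)[-2]:
                ambiguous = True
            ys, xs = np.nonzero(lab == main)
            v0n, v1n = v0 + ys.min(), v0 + ys.max()
            u0n, u1n = u0 + xs.min(), u0 + xs.max()
            u0, u1, v0, v1 = int(u0n), int(u1n), int(v0n), int(v1n)
            count = int(sizes.max())
    conf = min(1.0, count / EXPECTED_PART_PIXELS.get(part, 1000.0))
    return Box2D(u0=u0, v0=v0, u1=u1, v1=v1, confidence=conf, ambiguous=ambiguous)


# ---------------------------------------------------------------------------
# 3D body boxes


def init_body_box_3d(
    part_boxes: dict[str, Box2D],
    calibration: CalibrationSet,
    part: str,
    body_peaks: list[np.ndarray] | None = None,
) -> BodyBox3D:
    """Initialise a part's 3D box from triangulated 2D box centres.

    When body-height occupancy peaks are supplied, the ground-plane
    centre snaps to the peak nearest the triangulation (cross-camera
    fusion); the triangulated height is kept either way.
    """
    obs = [(calibration[cid], box.centre) for cid, box in part_boxes.items()]
    if len(obs) < 2:
        raise InsufficientViewsError(f"{part}: need >= 2 views to initialise")
    tri = triangulate_point(obs)
    centre = tri.point.copy()
    if body_peaks:
        pts = np.asarray(body_peaks, float)
        d = np.hypot(pts[:, 0] - centre[0], pts[:, 1] - centre[1])
        j = int(np.argmin(d))
        if d[j] < 1.0:
            centre[0], centre[1] = pts[j][0], pts[j][1]
    return BodyBox3D(part=part, centre=centre,
                     dimensions=np.array(PART_DIMENSIONS[part]))


def _project_box_rect(camera, corners):
    x_cam = corners @ camera.rotation.T + camera.translation
    if np.any(x_cam[:, 2] < 0.2):
        return None
    K = camera.intrinsic_matrix
    u = K[0, 0] * x_cam[:, 0] / x_cam[:, 2] + K[0, 2]
    v = K[1, 1] * x_cam[:, 1] / x_cam[:, 2] + K[1, 2]
    return u.min(), v.min(), u.max(), v.max()


def _rect_iou(a, b) -> float:
    ix = max(0.0, min(a[2], b[2]) - max(a[0], b[0]))
    iy = max(0.0, min(a[3], b[3]) - max(a[1], b[1]))
    inter = ix * iy
    if inter <= 0:
        return 0.0
    area_a = (a[2] - a[0]) * (a[3] - a[1])
    area_b = (b[2] - b[0]) * (b[3] - b[1])
    return inter / (area_a + area_b - inter)


def optimise_body_box(
    box: BodyBox3D,
    part_boxes: dict[str, Box2D],
    calibration: CalibrationSet,
    size_bound: float = 0.30,
    step0: float = 0.02,
    tol: float = 1e-3,
    min_iou: float = 0.1,
) -> BodyBox3D:
    """Coordinate-descent fit of centre and size against the 2D boxes.

    Maximises the mean over cameras of the IoU between the projected
    box's bounding rectangle and the observed part box; sizes are bounded
    to +-``size_bound`` of the part defaults.  Mean IoU below ``min_iou``
    marks the frame invalid (track-lost).
    """
    defaults = np.array(PART_DIMENSIONS[box.part])
    lo, hi = defaults * (1 - size_bound), defaults * (1 + size_bound)
    targets = {cid: (b.u0, b.v0, b.u1 + 1, b.v1 + 1)
               for cid, b in part_boxes.items()}

    def score(centre, dims):
        bb = np.clip(dims, lo, hi)
        signs = np.array([[sx, sy, sz] for sx in (-1, 1) for sy in (-1, 1)
                          for sz in (-1, 1)], float)
        corners = centre + 0.5 * signs * bb
        vals = []
        for cid, target in targets.items():
            rect = _project_box_rect(calibration[cid], corners)
            if rect is None:
                continue
            vals.append(_rect_iou(rect, target))
        return float(np.mean(vals)) if vals else 0.0

    centre = box.centre.copy()
    dims = np.clip(box.dimensions.copy(), lo, hi)
    best = score(centre, dims)
    step = step0
    while step >= tol:
        improved = False
        for i in range(3):
            for s in (step, -step):
                c = centre.copy()
                c[i] += s
                val = score(c, dims)
                if val > best + 1e-12:
                    best, centre = val, c
                    improved = True
            for s in (step, -step):
                d = dims.copy()
                d[i] = np.clip(d[i] + s, lo[i], hi[i])
                val = score(centre, d)
                if val > best + 1e-12:
                    best, dims = val, d
                    improved = True
        if not improved:
            step *= 0.5
    return BodyBox3D(part=box.part, centre=centre, dimensions=dims,
                     confidence=best, valid=best >= min_iou)


def track_body_part(
    boxes_per_frame: list[dict[str, Box2D]],
    calibration: CalibrationSet,
    part: str,
    body_peaks_per_frame: list[list[np.ndarray]] | None = None,
    min_views: int = 2,
) -> tuple[np.ndarray, np.ndarray]:
    """Frame-sequential 3D box tracking; returns (positions (N,3), valid).

    Each frame re-optimises from the previous pose (warm start); when an
    occupancy-peak list is provided the box must stay within a metre of
    some body-height peak ("continued existence"), and frames with too
    few views or a failed fit are marked invalid, re-initialising at the
    next usable frame.
    """
    n = len(boxes_per_frame)
    pos = np.full((n, 3), np.nan)
    valid = np.zeros(n, bool)
    current: BodyBox3D | None = None
    for f in range(n):
        boxes = boxes_per_frame[f]
        peaks = body_peaks_per_frame[f] if body_peaks_per_frame else None
        if len(boxes) < min_views:
            current = None
            continue
        try:
            if current is None:
                current = init_body_box_3d(boxes, calibration, part, peaks)
            fitted = optimise_body_box(current, boxes, calibration)
        except GeometryError:
            current = None
            continue
        if not fitted.valid:
            current = None
            continue
        if peaks:
            pts = np.asarray(peaks, float)
            d = np.hypot(pts[:, 0] - fitted.centre[0], pts[:, 1] - fitted.centre[1])
            if d.min() > 1.0:
                current = None
                continue
        current = fitted
        pos[f] = fitted.centre
        valid[f] = True
    return pos, valid


def com_from_boxes(
    head_positions: np.ndarray,
    head_valid: np.ndarray,
    torso_positions: np.ndarray,
    torso_valid: np.ndarray,
    weights: tuple[float, float] = (0.14, 0.86),
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Mass-weighted head/torso average: the athlete CoM proxy.

    Weights default to the approximate head and trunk shares of the
    segmental mass they stand in for and must sum to 1.  Frames with one
    part missing fall back to the other (flagged); frames with neither
    are invalid.
    """
    w_h, w_t = weights
    if not np.isclose(w_h + w_t, 1.0):
        raise ValueError("weights must sum to 1")
    n = len(torso_positions)
    out = np.full((n, 3), np.nan)
    valid = np.zeros(n, bool)
    partial = np.zeros(n, bool)
    for f in range(n):
        h, t = head_valid[f], torso_valid[f]
        if h and t:
            out[f] = w_h * head_positions[f] + w_t * torso_positions[f]
            valid[f] = True
        elif t:
            out[f] = torso_positions[f]
            valid[f] = True
            partial[f] = True
        elif h:
            out[f] = head_positions[f]
            valid[f] = True
            partial[f] = True
    return out, valid, partial


# ---------------------------------------------------------------------------
# sled pose


def fit_sled_pose(
    corner_observations: dict[int, list],
    calibration: CalibrationSet,
    model: SledModel,
    confidence_threshold: float = 0.5,
) -> SledPose | None:
    """Rigid pose from triangulated corner detections.

    ``corner_observations`` maps corner_id -> list of (camera_id, (u, v),
    confidence).  Low-confidence detections are gated out; corners seen
    by >= 2 cameras are triangulated and the pose solved by orthogonal
    Procrustes against the template.  Fewer than 3 corners leave the
    frame invalid (None).
    """
    pts_t, pts_w = [], []
    for corner_id, obs in sorted(corner_observations.items()):
        good = [(calibration[cid], np.asarray(uv, float))
                for cid, uv, conf in obs if conf >= confidence_threshold]
        if len(good) < 2:
            continue
        try:
            tri = triangulate_point(good)
        except GeometryError:
            continue
        pts_t.append(model.template_corners[corner_id])
        pts_w.append(tri.point)
    if len(pts_t) < 3:
        return None
    try:
        al = estimate_rigid_alignment(np.asarray(pts_t), np.asarray(pts_w))
    except DegenerateConfigurationError:
        return None
    centroid = al.rotation @ model.centroid + al.translation
    return SledPose(rotation=al.rotation, translation=al.translation,
                    centroid=centroid, rms_residual=al.rms_residual,
                    n_corners=len(pts_t))


# ---------------------------------------------------------------------------
# bi-directional Kalman smoothing


def kalman_smooth(
    positions: np.ndarray,
    valid: np.ndarray,
    fps: float,
    config: KalmanConfig | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Outlier-gated forward Kalman pass + RTS backward smoothing.

    Per-axis constant-velocity model with white-noise acceleration;
    measurements whose joint (3-dof) innovation Mahalanobis distance
    exceeds the configured gate are treated as missing, as are invalid
    frames, and bridged by prediction.  Returns (smoothed positions,
    smoothed velocities, output validity); frames before the first valid
    measurement stay invalid.
    """
    config = config or KalmanConfig()
    z = np.asarray(positions, float)
    valid = np.asarray(valid, bool) & np.isfinite(z).all(axis=1)
    n = len(z)
    idx = np.flatnonzero(valid)
    if idx.size < 2:
        raise InsufficientDataError("need >= 2 valid frames to smooth")
    dt = 1.0 / fps
    F = np.array([[1.0, dt], [0.0, 1.0]])
    q = config.accel_spectral_density
    Q = q * np.array([[dt**3 / 3.0, dt**2 / 2.0], [dt**2 / 2.0, dt]])
    R = config.measurement_sd**2
    H = np.array([1.0, 0.0])
    gate = chi2.ppf(config.gate_quantile, df=3)

    i0, i1 = idx[0], idx[1]
    x = np.zeros((n, 2, 3))
    P = np.zeros((n, 2, 2))
    xp = np.zeros((n, 2, 3))     # priors, needed by the RTS pass
    Pp = np.zeros((n, 2, 2))
    v0 = (z[i1] - z[i0]) / ((i1 - i0) * dt)
    x[i0] = np.stack([z[i0], v0])
    P[i0] = np.diag([R, config.init_var])
    xp[i0], Pp[i0] = x[i0], P[i0]
    used = np.zeros(n, bool)
    used[i0] = True
    gated = np.zeros(n, bool)

    for k in range(i0 + 1, n):
        xpred = F @ x[k - 1]
        Ppred = F @ P[k - 1] @ F.T + Q
        xp[k], Pp[k] = xpred, Ppred
        S = Ppred[0, 0] + R
        accept = False
        if valid[k]:
            innov = z[k] - xpred[0]
            d2 = float(np.sum(innov**2) / S)
            if d2 <= gate:
                accept = True
            else:
                gated[k] = True
        if accept:
            Kg = Ppred[:, 0] / S
            x[k] = xpred + np.outer(Kg, innov)
            IKH = np.eye(2) - np.outer(Kg, H)
            P[k] = IKH @ Ppred @ IKH.T + np.outer(Kg, Kg) * R  # Joseph form
            used[k] = True
        else:
            x[k], P[k] = xpred, Ppred

    xs = x.copy()
    Ps = P.copy()
    for k in range(n - 2, i0 - 1, -1):
        C = P[k] @ F.T @ np.linalg.inv(Pp[k + 1])
        xs[k] = x[k] + C @ (xs[k + 1] - xp[k + 1])
        Ps[k] = P[k] + C @ (Ps[k + 1] - Pp[k + 1]) @ C.T

    out_pos = np.full_like(z, np.nan)
    out_vel = np.full_like(z, np.nan)
    out_valid = np.zeros(n, bool)
    out_pos[i0:] = xs[i0:, 0, :]
    out_vel[i0:] = xs[i0:, 1, :]
    out_valid[i0:] = True
    return out_pos, out_vel, out_valid


def central_diff_velocity(positions: np.ndarray, fps: float) -> tuple[np.ndarray, np.ndarray]:
    """Finite central differences; one-sided at the ends (flagged).

    v_i = (p_{i+1} - p_{i-1}) * fps / 2 for interior frames — exact for
    linear and quadratic trajectories.
    """
    p = np.asarray(positions, float)
    if p.shape[0] < 3:
        raise InsufficientDataError("central differences need >= 3 frames")
    v = np.empty_like(p)
    v[1:-1] = (p[2:] - p[:-2]) * fps / 2.0
    v[0] = (p[1] - p[0]) * fps
    v[-1] = (p[-1] - p[-2]) * fps
    one_sided = np.zeros(p.shape[0], bool)
    one_sided[[0, -1]] = True
    return v, one_sided


def build_trajectory(
    positions: np.ndarray,
    valid: np.ndarray,
    fps: float,
    label: str,
    config: KalmanConfig | None = None,
) -> Trajectory:
    """Smooth a raw centroid series and differentiate it: the standard path."""
    n = len(positions)
    times = np.arange(n) / fps
    pos_s, vel_k, valid_s = kalman_smooth(positions, valid, fps, config)
    vel = np.full_like(pos_s, np.nan)
    i0 = int(np.flatnonzero(valid_s)[0])
    if n - i0 >= 3:
        vel[i0:], _ = central_diff_velocity(pos_s[i0:], fps)
    else:
        vel[i0:] = vel_k[i0:]
    return Trajectory(times=times, positions=pos_s, velocities=vel,
                      valid=valid_s, label=label,
                      flags={"gated_or_missing": int((~valid).sum())})
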