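"""Rasterise synthetic athletes (and sled) into part-label mask images.

The body is a set of labelled convex primitives — spheres for head and
hands, capsules for torso and limb segments, cuboids for the feet — and
the sled a cuboid occluder that is painted as *background* (the part
segmentation this emulates never labels the sled as foreground).
Primitives are painted in painter's order by centre depth, nearer
primitives overwriting farther ones; adequate for convex, rarely
interpenetrating bodies and much cheaper than a z-buffer.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy.spatial import ConvexHull, QhullError
from skimage.draw import disk, polygon

from .geometry import CalibrationSet, CameraModel
from .masks import PART_CODES, MaskSequence
from .synthetic import SceneTruth

_L = PART_CODES


@dataclass(frozen=True)
class BodyGeometry:
    """Primitive dimensions scaled from stature (all metres)."""

    stature: float = 1.80

    @property
    def head_radius(self):
        return 0.060 * self.stature

    @property
    def torso_radius(self):
        return 0.078 * self.stature

    @property
    def torso_length(self):
        return 0.30 * self.stature

    @property
    def thigh_length(self):
        return 0.25 * self.stature

    @property
    def shank_length(self):
        return 0.25 * self.stature

    @property
    def foot_dims(self):
        return (0.14 * self.stature, 0.050 * self.stature, 0.050 * self.stature)

    @property
    def hip_halfwidth(self):
        return 0.05 * self.stature

    @property
    def shoulder_halfwidth(self):
        return 0.105 * self.stature

    @property
    def limb_radius(self):
        return 0.038 * self.stature


def _knee_position(hip, ankle, l_thigh, l_shank):
    """Two-link IK: knee bows forward (+X) out of the hip-ankle chord."""
    hip = np.asarray(hip, float)
    ankle = np.asarray(ankle, float)
    d = np.linalg.norm(ankle - hip)
    if d < 1e-9:
        return (hip + ankle) / 2.0
    u = (ankle - hip) / d
    fwd = np.array([1.0, 0.0, 0.0])
    fwd = fwd - (fwd @ u) * u
    n = np.linalg.norm(fwd)
    fwd = fwd / n if n > 1e-9 else np.array([1.0, 0.0, 0.0])
    half = min(d / 2.0, l_thigh - 1e-6)
    e = np.sqrt(max(l_thigh**2 - half**2, 0.0))
    return hip + half * u + e * fwd


def body_primitives(truth: SceneTruth, t: float, geom: BodyGeometry):
    """Labelled primitive list for one instant.

    Each entry is ``(kind, label, *data)`` with kinds 'sphere'
    (centre, r), 'capsule' (a, b, r) and 'cuboid' (centre, dims).
    """
    p = truth.params
    g = geom
    com = truth.com_at(t)
    foot_l = truth.foot_at("left", t)
    foot_r = truth.foot_at("right", t)

    pelvis = np.array([com[0] - 0.05, 0.0, com[2] - 0.035])
    if p.posture == "bent":
        theta = np.deg2rad(25.0)
        pelvis = np.array([com[0] - 0.30, 0.0, com[2] + 0.13])
    else:
        zf = 0.55 * p.athlete_height
        crouch = min(max((zf - com[2]) / (0.12 * zf + 1e-9), 0.0), 1.0)
        theta = np.deg2rad(80.0 - 35.0 * crouch)
    torso_dir = np.array([np.cos(theta), 0.0, np.sin(theta)])
    neck = pelvis + g.torso_length * torso_dir
    head = neck + (g.head_radius + 0.05) * torso_dir

    prims = [
        ("capsule", _L["torso"], pelvis, neck, g.torso_radius),
        ("sphere", _L["head"], head, g.head_radius),
    ]

    fl, fw, fh = g.foot_dims
    for side, foot in (("left", foot_l), ("right", foot_r)):
        sgn = 1.0 if side == "left" else -1.0
        hip = pelvis + np.array([0.0, sgn * g.hip_halfwidth, 0.0])
        ankle = foot + np.array([-fl * 0.25, 0.0, fh * 0.8])
        knee = _knee_position(hip, ankle, g.thigh_length, g.shank_length)
        prims.append(("capsule", _L[f"thigh_{side}"], hip, knee, 0.039 * p.athlete_height))
        prims.append(("capsule", _L[f"shank_{side}"], knee, ankle, g.limb_radius))
        prims.append(("cuboid", _L[f"foot_{side}"],
                      foot + np.array([0.0, 0.0, fh / 2.0]), np.array([fl, fw, fh])))

    # arms: cosmetic swing opposite to the same-side leg; when pushing, the
    # sled-side hand stays on the sled handle
    phase = 2.0 * np.pi * p.base_step_frequency / 2.0 * (t + p.start_offset)
    sled_tr = truth.sled_translation_at(t)
    for side in ("left", "right"):
        sgn = 1.0 if side == "left" else -1.0
        shoulder = neck + np.array([0.0, sgn * g.shoulder_halfwidth, 0.0])
        on_sled = (
            sled_tr is not None and p.sled is not None and p.sled.side == side
        )
        if on_sled:
            hand = sled_tr + np.array([-p.sled.corner_half[0], 0.0, 0.05])
        else:
            sw = np.sin(phase) * sgn
            drop = np.array([0.25 * sw, 0.0, -0.40 + 0.10 * abs(sw)])
            if p.posture == "bent":
                drop = np.array([0.30 * sw, 0.0, -0.35])
            hand = shoulder + drop
        elbow = (shoulder + hand) / 2.0 + np.array([-0.06, 0.0, 0.0])
        prims.append(("capsule", _L[f"upper_arm_{side}"], shoulder, elbow, g.limb_radius))
        prims.append(("capsule", _L[f"lower_arm_{side}"], elbow, hand, g.limb_radius * 0.85))
        prims.append(("sphere", _L[f"hand_{side}"], hand, g.limb_radius))

    if sled_tr is not None:
        size = np.asarray(p.sled.size)
        centre = sled_tr - np.array([0.0, 0.0, size[2] / 2.0])
        prims.append(("cuboid", 0, centre, size))  # occluder, never foreground
    return prims


# ---------------------------------------------------------------------------
# rasterisation

_CUBE_SIGNS = np.array(
    [[sx, sy, sz] for sx in (-1, 1) for sy in (-1, 1) for sz in (-1, 1)], float
)


def _paint_sphere(img, cam: CameraModel, centre, r, label):
    x_cam = cam.rotation @ centre + cam.translation
    z = x_cam[2]
    if z < 0.2:
        return
    K = cam.intrinsic_matrix
    u = K[0, 0] * x_cam[0] / z + K[0, 2]
    v = K[1, 1] * x_cam[1] / z + K[1, 2]
    pr = K[0, 0] * r / z
    rr, cc = disk((v, u), pr, shape=img.shape)
    img[rr, cc] = label


def _paint_capsule(img, cam: CameraModel, a, b, r, label):
    K = cam.intrinsic_matrix
    pa = cam.rotation @ a + cam.translation
    pb = cam.rotation @ b + cam.translation
    if pa[2] < 0.2 or pb[2] < 0.2:
        return
    ua = np.array([K[0, 0] * pa[0] / pa[2] + K[0, 2], K[1, 1] * pa[1] / pa[2] + K[1, 2]])
    ub = np.array([K[0, 0] * pb[0] / pb[2] + K[0, 2], K[1, 1] * pb[1] / pb[2] + K[1, 2]])
    ra = K[0, 0] * r / pa[2]
    rb = K[0, 0] * r / pb[2]
    h, w = img.shape
    rmax = max(ra, rb)
    u0 = int(np.floor(min(ua[0], ub[0]) - rmax))
    u1 = int(np.ceil(max(ua[0], ub[0]) + rmax)) + 1
    v0 = int(np.floor(min(ua[1], ub[1]) - rmax))
    v1 = int(np.ceil(max(ua[1], ub[1]) + rmax)) + 1
    u0, v0 = max(u0, 0), max(v0, 0)
    u1, v1 = min(u1, w), min(v1, h)
    if u0 >= u1 or v0 >= v1:
        return
    uu, vv = np.meshgrid(np.arange(u0, u1), np.arange(v0, v1))
    d = ub - ua
    len2 = d @ d
    px = uu - ua[0]
    py = vv - ua[1]
    if len2 < 1e-12:
        t = np.zeros_like(px, float)
    else:
        t = np.clip((px * d[0] + py * d[1]) / len2, 0.0, 1.0)
    dx = px - t * d[0]
    dy = py - t * d[1]
    rad = ra + (rb - ra) * t
    inside = dx * dx + dy * dy <= rad * rad
    img[v0:v1, u0:u1][inside] = label


def _paint_cuboid(img, cam: CameraModel, centre, dims, label):
    corners = centre + 0.5 * _CUBE_SIGNS * np.asarray(dims)
    x_cam = corners @ cam.rotation.T + cam.translation
    if np.any(x_cam[:, 2] < 0.2):
        return
    K = cam.intrinsic_matrix
    u = K[0, 0] * x_cam[:, 0] / x_cam[:, 2] + K[0, 2]
    v = K[1, 1] * x_cam[:, 1] / x_cam[:, 2] + K[1, 2]
    pts = np.column_stack([u, v])
    try:
        hull = ConvexHull(pts)
        poly = pts[hull.vertices]
    except QhullError:
        return
    rr, cc = polygon(poly[:, 1], poly[:, 0], shape=img.shape)
    img[rr, cc] = label


def rasterise_frame(cam: CameraModel, prims) -> np.ndarray:
    """Paint primitives far-to-near into a fresh label image."""
    w, h = cam.image_size
    img = np.zeros((h, w), np.uint8)
    depths = []
    for prim in prims:
        kind = prim[0]
        if kind == "sphere":
            c = prim[2]
        elif kind == "capsule":
            c = (prim[2] + prim[3]) / 2.0
        else:
            c = prim[2]
        depths.append((cam.rotation @ np.asarray(c, float) + cam.translation)[2])
    order = np.argsort(depths)[::-1]
    for i in order:
        kind, label = prims[i][0], prims[i][1]
        if kind == "sphere":
            _paint_sphere(img, cam, prims[i][2], prims[i][3], label)
        elif kind == "capsule":
            _paint_capsule(img, cam, prims[i][2], prims[i][3], prims[i][4], label)
        else:
            _paint_cuboid(img, cam, prims[i][2], prims[i][3], label)
    return img


class RenderedMaskSequence(MaskSequence):
    """Lazy mask provider rendering frames from scene truth on demand.

    The per-frame primitive list is cached so the (typically 9) cameras
    sharing a frame build the body pose only once.
    """

    def __init__(self, truth: SceneTruth, calibration: CalibrationSet,
                 geometry: BodyGeometry | None = None):
        super().__init__(calibration.camera_ids, truth.n_frames, truth.fps)
        self.truth = truth
        self.calibration = calibration
        self.geometry = geometry or BodyGeometry(stature=truth.params.athlete_height)
        self._prims = lru_cache(maxsize=64)(self._build_prims)

    def _build_prims(self, index: int):
        t = index / self.fps
        return body_primitives(self.truth, t, self.geometry)

    def frame(self, camera_id: str, index: int) -> np.ndarray:
        return rasterise_frame(self.calibration[camera_id], self._prims(index))


# ---------------------------------------------------------------------------
# sled corner detections (CNN stand-in)


def _ray_capsule_occluded(cam_centre, target, seg_a, seg_b, radius):
    """True where the cam->target segment passes through a capsule (vectorised over frames)."""
    d = target - cam_centre  # (T, 3)
    # sample points along the ray and test distance to the capsule axis
    ts = np.linspace(0.05, 0.95, 12)
    occluded = np.zeros(target.shape[0], bool)
    ab = seg_b - seg_a
    ab2 = np.sum(ab * ab, axis=1, keepdims=True) + 1e-12
    for s in ts:
        p = cam_centre + s * d
        u = np.clip(np.sum((p - seg_a) * ab, axis=1, keepdims=True) / ab2, 0.0, 1.0)
        q = seg_a + u * ab
        occluded |= np.sum((p - q) ** 2, axis=1) <= radius**2
    return occluded


def sled_corner_detections(truth: SceneTruth, calibration: CalibrationSet,
                           geometry: BodyGeometry | None = None) -> pd.DataFrame | None:
    """Per-frame 2D sled-corner detections with occlusion-aware confidence.

    Confidence is 1.0 for an unoccluded corner and 0.2 when the torso or
    a leg segment lies between camera and corner (emulating a corner
    detector confused by the athlete).
    """
    if truth.params.sled is None:
        return None
    g = geometry or BodyGeometry(stature=truth.params.athlete_height)
    times = truth.times
    n = len(times)
    corners = np.array([truth.sled_corners_at(t) for t in times])  # (T, 4, 3)

    # occluder segments per frame: torso, thighs, shanks
    segs = {"a": [], "b": [], "r": []}
    for t in times:
        prims = body_primitives(truth, t, g)
        a_list, b_list, r_list = [], [], []
        for prim in prims:
            if prim[0] == "capsule" and prim[1] in (
                _L["torso"], _L["thigh_left"], _L["thigh_right"],
                _L["shank_left"], _L["shank_right"],
            ):
                a_list.append(prim[2])
                b_list.append(prim[3])
                r_list.append(prim[4])
        segs["a"].append(a_list)
        segs["b"].append(b_list)
        segs["r"].append(r_list)
    seg_a = np.array(segs["a"])  # (T, S, 3)
    seg_b = np.array(segs["b"])
    seg_r = np.array(segs["r"])  # (T, S)

    records = []
    for cam in calibration:
        cc = cam.centre
        for corner_id in range(4):
            target = corners[:, corner_id, :]
            occ = np.zeros(n, bool)
            for s in range(seg_a.shape[1]):
                occ |= _ray_capsule_occluded(cc, target, seg_a[:, s], seg_b[:, s],
                                             seg_r[:, s])
            x_cam = target @ cam.rotation.T + cam.translation
            z = x_cam[:, 2]
            K = cam.intrinsic_matrix
            with np.errstate(divide="ignore", invalid="ignore"):
                u = K[0, 0] * x_cam[:, 0] / z + K[0, 2]
                v = K[1, 1] * x_cam[:, 1] / z + K[1, 2]
            w, h = cam.image_size
            visible = (z > 0.2) & (u >= 0) & (u <= w - 1) & (v >= 0) & (v <= h - 1)
            conf = np.where(occ, 0.2, 1.0)
            for i in np.flatnonzero(visible):
                records.append(
                    (i, cam.camera_id, corner_id, float(u[i]), float(v[i]),
                     float(conf[i]))
                )
    return pd.DataFrame(
        records, columns=["frame", "camera_id", "corner_id", "u_px", "v_px", "confidence"]
    )
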