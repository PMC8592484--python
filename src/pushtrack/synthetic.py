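"""Synthetic multi-camera push-start / sprint scenes with exhaustive truth.

The generator emulates the study set-up this package targets: a ring of
frame-locked 200 Hz cameras around a ~10 m capture volume, an athlete
accelerating through it (optionally pushing a low rigid sled), and
per-camera part-segmentation masks standing in for CNN output.  Because
the capture volume is short, a trial covers a handful of steps; longer
step series are built from several trials entering the volume at
different phases of the acceleration, mirroring how staggered start
lines are used on a real track.

Athlete forward motion follows the monoexponential sprint-acceleration
model v(t) = v_max (1 - exp(-t / tau)) measured from the block start;
a trial's capture window opens ``start_offset`` seconds into the
acceleration.  Step events are placed so that each step's length is
(approximately) the local velocity divided by the base step frequency,
scaled by per-leg multipliers to create controllable asymmetry.  Stance
feet are exactly stationary between touchdown and toe-off; swing feet
follow a smooth path with sinusoidal vertical lift.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.ndimage import binary_erosion, grey_dilation
from scipy.optimize import brentq

from .geometry import CalibrationSet, look_at_camera
from .masks import PART_CODES, MaskSequence


@dataclass(frozen=True)
class SledSpec:
    """Rigid sled geometry: a low cuboid with four detectable top corners."""

    side: str = "right"  # which side of the athlete the sled runs on
    size: tuple[float, float, float] = (1.0, 0.55, 0.15)  # m
    corner_half: tuple[float, float] = (0.45, 0.25)  # template corner extent, m
    lateral_offset: float = 0.75  # m from athlete centreline
    forward_offset: float = 0.30  # m ahead of athlete CoM

    @property
    def template_corners(self) -> np.ndarray:
        hx, hy = self.corner_half
        return np.array(
            [[-hx, -hy, 0.0], [hx, -hy, 0.0], [hx, hy, 0.0], [-hx, hy, 0.0]]
        )


@dataclass(frozen=True)
class GaitParams:
    """Study conditions for one simulated trial."""

    v_max: float = 8.0            # asymptotic sprint velocity, m/s
    tau: float = 1.2              # acceleration time constant, s
    base_step_frequency: float = 4.0   # Hz at which SL tracks v / f
    gct_fraction: float = 0.45    # ground contact fraction of step time
    sl_multipliers: tuple[float, float] = (1.0, 1.0)   # (left, right)
    gct_multipliers: tuple[float, float] = (1.0, 1.0)  # (left, right)
    athlete_height: float = 1.80  # m
    swing_lift: float = 0.45      # peak swing-foot sole height, m
    stance_width: float = 0.10    # lateral foot offset from centreline, m
    start_offset: float = 1.0     # s into the acceleration when capture opens
    x_start: float = 1.0          # athlete CoM X at capture start, m
    sled: SledSpec | None = None
    seed: int = 0

    def __post_init__(self):
        if not 0.0 < self.gct_fraction < 1.0:
            raise ValueError("gct_fraction must lie in (0, 1)")
        if self.v_max <= 0 or self.tau <= 0:
            raise ValueError("v_max and tau must be positive")

    @property
    def posture(self) -> str:
        return "bent" if self.sled is not None else "upright"

    def leg_index(self, foot: str) -> int:
        return 0 if foot == "left" else 1


def _x_abs(p: GaitParams, ta: np.ndarray | float):
    """CoM forward displacement since the block start (closed form)."""
    ta = np.asarray(ta, float)
    return p.v_max * (ta + p.tau * (np.exp(-ta / p.tau) - 1.0))


def _v_abs(p: GaitParams, ta):
    return p.v_max * (1.0 - np.exp(-np.asarray(ta, float) / p.tau))


@dataclass
class SceneTruth:
    """Ground truth for one trial: CoM, sled, contacts and step table."""

    params: GaitParams
    fps: float
    n_frames: int
    times: np.ndarray           # (N,) capture-relative seconds
    com_pos: np.ndarray         # (N, 3)
    com_vel: np.ndarray         # (N, 3) analytic derivative
    contacts: pd.DataFrame      # foot, td_time, to_time, td_frame, to_frame, x, y, observed
    steps: pd.DataFrame         # per consecutive contact pair
    sled_pos: np.ndarray | None = None
    sled_vel: np.ndarray | None = None

    # -- continuous kinematics -------------------------------------------
    def com_at(self, t: float) -> np.ndarray:
        p = self.params
        ta = t + p.start_offset
        x = p.x_start + float(_x_abs(p, ta) - _x_abs(p, p.start_offset))
        z = _com_height(p, t)
        return np.array([x, 0.0, z])

    def com_velocity_at(self, t: float) -> np.ndarray:
        p = self.params
        return np.array([float(_v_abs(p, t + p.start_offset)), 0.0,
                         _com_height_rate(p, t)])

    def foot_at(self, side: str, t: float) -> np.ndarray:
        """Sole reference point (x, y, z) of one foot at time t."""
        c = self.contacts[self.contacts.foot == side]
        td = c.td_time.to_numpy()
        to = c.to_time.to_numpy()
        x = c.x.to_numpy()
        y = c.y.to_numpy()
        if len(td) == 0:
            return np.array([self.params.x_start, 0.0, 0.0])
        if t <= td[0]:
            return np.array([x[0], y[0], 0.0])
        j = int(np.searchsorted(td, t, side="right") - 1)
        if t <= to[j] or j == len(td) - 1:
            return np.array([x[j], y[j], 0.0])
        u = (t - to[j]) / (td[j + 1] - to[j])
        u = min(max(u, 0.0), 1.0)
        ease = 0.5 * (1.0 - np.cos(np.pi * u))
        return np.array(
            [x[j] + (x[j + 1] - x[j]) * ease,
             y[j] + (y[j + 1] - y[j]) * ease,
             self.params.swing_lift * np.sin(np.pi * u)]
        )

    def sled_translation_at(self, t: float) -> np.ndarray | None:
        s = self.params.sled
        if s is None:
            return None
        com = self.com_at(t)
        y = -s.lateral_offset if s.side == "right" else s.lateral_offset
        return np.array([com[0] + s.forward_offset, y, s.size[2]])

    def sled_corners_at(self, t: float) -> np.ndarray | None:
        tr = self.sled_translation_at(t)
        if tr is None:
            return None
        return self.params.sled.template_corners + tr


def _com_height(p: GaitParams, t: float) -> float:
    if p.posture == "bent":
        return 0.55 * 0.7 * p.athlete_height
    zf = 0.55 * p.athlete_height
    zs = 0.88 * zf
    ta = t + p.start_offset
    return float(zf - (zf - zs) * np.exp(-ta / 1.2))


def _com_height_rate(p: GaitParams, t: float) -> float:
    if p.posture == "bent":
        return 0.0
    zf = 0.55 * p.athlete_height
    zs = 0.88 * zf
    ta = t + p.start_offset
    return float((zf - zs) / 1.2 * np.exp(-ta / 1.2))


def duration_for_distance(params: GaitParams, distance: float) -> float:
    """Capture duration for the CoM to advance ``distance`` metres."""
    p = params

    def g(t):
        return float(_x_abs(p, t + p.start_offset) - _x_abs(p, p.start_offset)) - distance

    hi = 1.0
    while g(hi) < 0:
        hi *= 2.0
        if hi > 1e4:
            raise ValueError("distance unreachable")
    return float(brentq(g, 1e-9, hi))


def simulate_gait(params: GaitParams, duration: float, fps: float = 200.0) -> SceneTruth:
    """Generate one trial's ground truth.

    Contacts are scheduled from the block start so a trial can open
    mid-acceleration; contacts whose stance straddles the capture window
    are retained (flagged unobserved) so the swing kinematics are defined
    everywhere inside the window.
    """
    p = params
    n_frames = int(round(duration * fps))
    if n_frames < 3:
        raise ValueError("duration * fps must cover at least 3 frames")

    # --- contact schedule in absolute (block) time ---
    first_td_abs = 0.25
    tds_abs, feet = [first_td_abs], ["left"]
    horizon = p.start_offset + duration + 0.6
    while tds_abs[-1] < horizon:
        td = tds_abs[-1]
        foot = feet[-1]
        sl_target = max(_v_abs(p, td), 0.3) / p.base_step_frequency
        sl_target *= p.sl_multipliers[p.leg_index(foot)]

        def g(T, td=td, sl=sl_target):
            return float(_x_abs(p, td + T) - _x_abs(p, td)) - sl

        st = float(brentq(g, 1e-4, 10.0))
        tds_abs.append(td + st)
        feet.append("right" if foot == "left" else "left")

    tds_abs = np.asarray(tds_abs)
    sts = np.diff(tds_abs)
    sts = np.append(sts, sts[-1])
    gct_mul = np.array([p.gct_multipliers[p.leg_index(f)] for f in feet])
    gcts = p.gct_fraction * gct_mul * sts
    tos_abs = tds_abs + gcts

    # first contact sits under the CoM at mid-stance; subsequent contacts
    # advance by exactly the per-step length targets, so configured
    # asymmetries appear in the truth step lengths by construction (the
    # foot keeps a fixed offset to the CoM at touchdown because touchdown
    # times were solved from the same targets)
    sl_targets = np.array([
        max(_v_abs(p, td), 0.3) / p.base_step_frequency
        * p.sl_multipliers[p.leg_index(f)]
        for td, f in zip(tds_abs, feet)
    ])
    xs = np.empty(len(tds_abs))
    xs[0] = p.x_start + float(_x_abs(p, tds_abs[0] + gcts[0] / 2.0)
                              - _x_abs(p, p.start_offset))
    xs[1:] = xs[0] + np.cumsum(sl_targets[:-1])
    ys = np.where([f == "left" for f in feet], p.stance_width, -p.stance_width)

    td_cap = tds_abs - p.start_offset
    to_cap = tos_abs - p.start_offset
    keep = (to_cap >= -0.4) & (td_cap <= duration + 0.4)
    contacts = pd.DataFrame(
        {
            "foot": np.asarray(feet)[keep],
            "td_time": td_cap[keep],
            "to_time": to_cap[keep],
            "td_frame": td_cap[keep] * fps,
            "to_frame": to_cap[keep] * fps,
            "x": xs[keep],
            "y": ys[keep],
            "observed": (td_cap[keep] >= 0) & (to_cap[keep] <= duration),
        }
    ).reset_index(drop=True)

    rows = []
    for i in range(len(contacts) - 1):
        a, b = contacts.iloc[i], contacts.iloc[i + 1]
        st = b.td_time - a.td_time
        gct = a.to_time - a.td_time
        rows.append(
            {
                "step_index": i,
                "leading_foot": a.foot,
                "td_time": a.td_time,
                "to_time": a.to_time,
                "next_td_time": b.td_time,
                "sl": b.x - a.x,
                "st": st,
                "gct": gct,
                "ft": st - gct,
                "sf": 1.0 / st,
                "sv": (b.x - a.x) / st,
                "observed": bool(a.observed and b.observed),
            }
        )
    steps = pd.DataFrame(rows)

    times = np.arange(n_frames) / fps
    ta = times + p.start_offset
    x = p.x_start + _x_abs(p, ta) - float(_x_abs(p, p.start_offset))
    z = np.array([_com_height(p, t) for t in times])
    vz = np.array([_com_height_rate(p, t) for t in times])
    com_pos = np.column_stack([x, np.zeros(n_frames), z])
    com_vel = np.column_stack([_v_abs(p, ta), np.zeros(n_frames), vz])

    truth = SceneTruth(
        params=p, fps=fps, n_frames=n_frames, times=times,
        com_pos=com_pos, com_vel=com_vel, contacts=contacts, steps=steps,
    )
    if p.sled is not None:
        sled_pos = np.array([truth.sled_translation_at(t) for t in times])
        sled_vel = com_vel.copy()
        sled_vel[:, 2] = 0.0
        truth.sled_pos = sled_pos
        truth.sled_vel = sled_vel
    return truth


# ---------------------------------------------------------------------------
# camera ring


def make_camera_ring(
    n: int = 9,
    x_range: tuple[float, float] = (0.0, 10.0),
    track_halfwidth: float = 1.0,
    image_size: tuple[int, int] = (960, 540),
    lateral_offset: float = 5.0,
    height: float = 1.5,
) -> CalibrationSet:
    """Cameras alternating sides of the track, aimed at the volume centre.

    Intrinsics give ~90 degrees horizontal field of view at the requested
    resolution (focal length = half the image width).
    """
    if n < 2:
        raise ValueError("a camera ring needs at least 2 cameras")
    x0, x1 = x_range
    xs = np.linspace(x0, x1, n)
    centre = np.array([(x0 + x1) / 2.0, 0.0, 1.0])
    w, _ = image_size
    cams = []
    for i, x in enumerate(xs):
        side = 1.0 if i % 2 == 0 else -1.0
        pos = np.array([x, side * (track_halfwidth + lateral_offset), height])
        cams.append(look_at_camera(f"{i:02d}", pos, centre, w / 2.0, image_size))
    return CalibrationSet(cameras=tuple(cams))


# ---------------------------------------------------------------------------
# mask corruption


@dataclass(frozen=True)
class NoiseSpec:
    """Segmentation-degradation model applied per camera frame."""

    boundary_px: int = 0       # random erosion/dilation up to +-k pixels
    dropout_p: float = 0.0     # probability a camera frame is lost entirely
    salt_blobs: int = 0        # spurious foreground blobs per frame
    salt_radius: tuple[int, int] = (2, 6)

    @property
    def is_identity(self) -> bool:
        return self.boundary_px == 0 and self.dropout_p == 0.0 and self.salt_blobs == 0


class CorruptedMaskSequence(MaskSequence):
    """Lazy wrapper applying ``NoiseSpec`` deterministically per (camera, frame)."""

    def __init__(self, base: MaskSequence, noise: NoiseSpec, seed: int):
        super().__init__(base.camera_ids, base.n_frames, base.fps)
        self.base = base
        self.noise = noise
        self.seed = int(seed)

    def frame(self, camera_id: str, index: int) -> np.ndarray:
        labels = self.base.frame(camera_id, index)
        if self.noise.is_identity:
            return labels
        cam_idx = self.camera_ids.index(camera_id)
        rng = np.random.default_rng((self.seed, cam_idx, index))
        return _corrupt_frame(labels, self.noise, rng)


def _corrupt_frame(labels: np.ndarray, noise: NoiseSpec, rng) -> np.ndarray:
    out = labels.copy()
    if noise.dropout_p > 0 and rng.random() < noise.dropout_p:
        return np.zeros_like(out)
    if noise.boundary_px > 0:
        k = int(rng.integers(-noise.boundary_px, noise.boundary_px + 1))
        if k != 0 and out.any():
            rows = np.flatnonzero(out.any(axis=1))
            cols = np.flatnonzero(out.any(axis=0))
            pad = abs(k) + 1
            r0, r1 = max(rows[0] - pad, 0), min(rows[-1] + pad + 1, out.shape[0])
            c0, c1 = max(cols[0] - pad, 0), min(cols[-1] + pad + 1, out.shape[1])
            win = out[r0:r1, c0:c1]
            if k > 0:
                win[:] = grey_dilation(win, size=(2 * k + 1, 2 * k + 1))
            else:
                fg = binary_erosion(win > 0, iterations=-k)
                win[~fg] = 0
    if noise.salt_blobs > 0:
        h, w = out.shape
        for _ in range(noise.salt_blobs):
            cy = rng.integers(0, h)
            cx = rng.integers(0, w)
            r = rng.integers(noise.salt_radius[0], noise.salt_radius[1] + 1)
            lab = rng.integers(1, max(PART_CODES.values()) + 1)
            yy, xx = np.ogrid[max(cy - r, 0):min(cy + r + 1, h),
                              max(cx - r, 0):min(cx + r + 1, w)]
            out[max(cy - r, 0):min(cy + r + 1, h),
                max(cx - r, 0):min(cx + r + 1, w)][
                (yy - cy) ** 2 + (xx - cx) ** 2 <= r * r] = lab
    return out


def corrupt_masks(masks: MaskSequence, noise: NoiseSpec, seed: int) -> MaskSequence:
    """Return a lazily corrupted view of ``masks`` (identity spec passes through)."""
    if noise.is_identity:
        return masks
    return CorruptedMaskSequence(masks, noise, seed)


def write_scene(truth: SceneTruth, calibration: CalibrationSet, scene_dir,
                noise: "NoiseSpec | None" = None, seed: int = 0) -> None:
    """Write a renderable trial to disk in the pipeline's input layout.

    Produces calibration.json, cam*/frame*.png label masks (optionally
    corrupted), sled_detections.csv when a sled is present, and
    truth_steps.csv / truth_com.csv reference tables.
    """
    from pathlib import Path

    from .geometry import save_calibration
    from .masks import write_mask_sequence

    scene_dir = Path(scene_dir)
    scene_dir.mkdir(parents=True, exist_ok=True)
    seq, detections = render_masks(truth, calibration)
    if noise is not None and not noise.is_identity:
        seq = corrupt_masks(seq, noise, seed)
    save_calibration(calibration, scene_dir / "calibration.json")
    write_mask_sequence(seq, scene_dir)
    if detections is not None:
        detections.to_csv(scene_dir / "sled_detections.csv", index=False)
    truth.steps.to_csv(scene_dir / "truth_steps.csv", index=False)
    com = pd.DataFrame(
        {
            "frame": np.arange(truth.n_frames), "time_s": truth.times,
            "x": truth.com_pos[:, 0], "y": truth.com_pos[:, 1],
            "z": truth.com_pos[:, 2],
            "vx": truth.com_vel[:, 0], "vy": truth.com_vel[:, 1],
            "vz": truth.com_vel[:, 2],
        }
    )
    com.to_csv(scene_dir / "truth_com.csv", index=False)


def render_masks(truth: SceneTruth, calibration: CalibrationSet, geometry=None):
    """Render a trial into lazy per-camera label masks plus sled detections.

    Convenience re-export; see :mod:`pushtrack.render` for the renderer.
    """
    from .render import RenderedMaskSequence, sled_corner_detections

    seq = RenderedMaskSequence(truth, calibration, geometry)
    detections = sled_corner_detections(truth, calibration, seq.geometry)
    return seq, detections
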