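"""Touchdown / toe-off refinement via foot-box fitting and slice tracking.

A contact candidate from the occupancy stage gives an approximate stance
location and a mid-stance anchor frame.  Refinement proceeds per event:

1. an approximately foot-sized 3D box, long axis along the direction of
   travel, is initialised at the candidate location and its ground-plane
   centre optimised to fit the foot-labelled pixels in all camera views;
2. the box is projected into each view, the projected region split into
   vertical slices ordered heel -> toe, and each slice reduced to 1D
   columns of intensity and vertical (Sobel) gradient by horizontal
   averaging;
3. slices are tracked frame to frame by the integer vertical shift
   minimising the sum of squared column differences (parabolic subpixel
   refinement), accumulating outward from the mid-stance anchor;
4. toe-off is the last frame before the toe-end slice's cumulative
   vertical displacement exceeds a threshold when tracking forwards, and
   touchdown the last such frame when tracking backwards — i.e. the
   boundary frame on the stationary side of the first supra-threshold
   displacement.  Event frames are fused across cameras by the median,
   half-frame ties rounding toward mid-stance.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .geometry import (
    CalibrationSet,
    CameraModel,
    GeometryError,
    project_points,
    triangulate_point,
)
from .masks import FOOT_LABELS, MaskSequence
from .occupancy import ContactCandidate, _BoxSums


class OutOfViewError(ValueError):
    """Requested region projects entirely outside the image."""


@dataclass(frozen=True)
class FootEventConfig:
    box_dims: tuple[float, float, float] = (0.30, 0.15, 0.12)  # L x W x H, m
    n_slices: int = 8
    max_shift_px: int = 15
    delta_px: float = 2.0          # displacement threshold marking movement
    max_step_px: float = 6.0       # plausible displacement change per frame
    pad_px: int = 6                # rect padding so a lifting foot stays inside
    search_s: float = 0.5          # how far beyond the candidate to scan
    onset_window_s: float = 0.04   # accepted onset distance from candidate bounds
    descent_step: float = 0.01     # m, initial coordinate-descent step
    descent_tol: float = 1e-3      # m
    min_views: int = 2


@dataclass
class FootBox:
    """Foot-sized 3D box; long axis along world X, floor on the ground."""

    centre: np.ndarray
    dimensions: tuple[float, float, float] = (0.30, 0.15, 0.12)
    foot_side: str | None = None
    low_confidence: bool = False

    def __post_init__(self):
        self.centre = np.asarray(self.centre, float)
        if any(d <= 0 for d in self.dimensions):
            raise ValueError("box dimensions must be positive")

    @property
    def corners(self) -> np.ndarray:
        signs = np.array([[sx, sy, sz] for sx in (-1, 1) for sy in (-1, 1)
                          for sz in (-1, 1)], float)
        return self.centre + 0.5 * signs * np.asarray(self.dimensions)


@dataclass
class SliceProfile:
    """Per-slice 1D intensity and vertical-gradient columns for one frame."""

    intensity: np.ndarray  # (n_slices, H)
    gradient: np.ndarray   # (n_slices, H)
    rect: tuple[int, int, int, int]  # u0, v0, u1, v1 (half-open)
    heel_to_toe: bool      # True if slice 0 is the heel end


@dataclass
class ContactEvent:
    foot_side: str
    td_frame: int
    to_frame: int
    td_time: float
    to_time: float
    location: np.ndarray
    source: ContactCandidate | None = None
    flags: list[str] = field(default_factory=list)

    def __post_init__(self):
        if self.td_frame >= self.to_frame:
            raise ValueError("touchdown must precede toe-off")


# ---------------------------------------------------------------------------
# foot box fitting


def _project_rect(camera: CameraModel, corners: np.ndarray, pad: int = 0):
    """Axis-aligned pixel rect of projected corners, clipped; None if unusable.

    ``pad`` extends the rect vertically only, so a lifting foot stays in
    view without diluting the heel/toe end slices with background.
    """
    x_cam = corners @ camera.rotation.T + camera.translation
    if np.any(x_cam[:, 2] < 0.05):
        return None
    K = camera.intrinsic_matrix
    u = K[0, 0] * x_cam[:, 0] / x_cam[:, 2] + K[0, 2]
    v = K[1, 1] * x_cam[:, 1] / x_cam[:, 2] + K[1, 2]
    w, h = camera.image_size
    u0 = int(np.floor(u.min()))
    u1 = int(np.ceil(u.max())) + 1
    v0 = int(np.floor(v.min())) - pad
    v1 = int(np.ceil(v.max())) + 1 + pad
    u0c, u1c = max(u0, 0), min(u1, w)
    v0c, v1c = max(v0, 0), min(v1, h)
    if u0c >= u1c or v0c >= v1c:
        return None
    return u0c, v0c, u1c, v1c


def _silhouette_centroid(camera: CameraModel, box: FootBox):
    """Area centroid of the box's projected convex hull, or None."""
    from scipy.spatial import ConvexHull, QhullError

    x_cam = box.corners @ camera.rotation.T + camera.translation
    if np.any(x_cam[:, 2] < 0.05):
        return None
    K = camera.intrinsic_matrix
    u = K[0, 0] * x_cam[:, 0] / x_cam[:, 2] + K[0, 2]
    v = K[1, 1] * x_cam[:, 1] / x_cam[:, 2] + K[1, 2]
    pts = np.column_stack([u, v])
    try:
        hull = ConvexHull(pts)
    except QhullError:
        return None
    poly = pts[hull.vertices]
    x, y = poly[:, 0], poly[:, 1]
    xn, yn = np.roll(x, -1), np.roll(y, -1)
    cross = x * yn - xn * y
    area = cross.sum() / 2.0
    if abs(area) < 1e-9:
        return None
    cx = np.sum((x + xn) * cross) / (6.0 * area)
    cy = np.sum((y + yn) * cross) / (6.0 * area)
    return np.array([cx, cy])


def fit_foot_box(
    candidate: ContactCandidate,
    masks: dict[str, np.ndarray],
    calibration: CalibrationSet,
    config: FootEventConfig | None = None,
) -> FootBox:
    """Optimise the box's ground-plane centre to cover foot-labelled pixels.

    The objective is the mean, over cameras seeing the box, of the
    fraction of the projected rectangle covered by foot pixels, maximised
    by coordinate descent (step halved on failure until the tolerance).
    Because the box is deliberately larger than a foot, that objective is
    flat over small translations, so the centre is then refined by
    triangulating the per-camera centroids of the winning foot label
    inside the fitted projection.  With foot pixels visible in fewer
    than ``min_views`` cameras the unrefined box is returned flagged
    low-confidence.
    """
    config = config or FootEventConfig()
    dims = config.box_dims
    centre0 = np.array([candidate.location[0], candidate.location[1], dims[2] / 2.0])

    sums = {}
    n_with_foot = 0
    for cam in calibration:
        labels = masks.get(cam.camera_id)
        if labels is None:
            continue
        foot = (labels == FOOT_LABELS[0]) | (labels == FOOT_LABELS[1])
        box = _BoxSums(foot)
        sums[cam.camera_id] = box
        if not box.empty:
            n_with_foot += 1

    if n_with_foot < config.min_views:
        return FootBox(centre=centre0, dimensions=dims, low_confidence=True)

    def score(cx, cy):
        centre = np.array([cx, cy, dims[2] / 2.0])
        fb = FootBox(centre=centre, dimensions=dims)
        vals = []
        for cam in calibration:
            if cam.camera_id not in sums:
                continue
            rect = _project_rect(cam, fb.corners)
            if rect is None:
                continue
            u0, v0, u1, v1 = rect
            area = (u1 - u0) * (v1 - v0)
            s = sums[cam.camera_id].rect_sums(
                np.array(u0), np.array(u1), np.array(v0), np.array(v1))
            vals.append(float(s) / area)
        return float(np.mean(vals)) if vals else 0.0

    cx, cy = float(centre0[0]), float(centre0[1])
    best = score(cx, cy)
    step = config.descent_step
    while step >= config.descent_tol:
        improved = False
        for dx, dy in ((step, 0), (-step, 0), (0, step), (0, -step)):
            s = score(cx + dx, cy + dy)
            if s > best + 1e-12:
                best, cx, cy = s, cx + dx, cy + dy
                improved = True
        if not improved:
            step *= 0.5

    box = FootBox(centre=np.array([cx, cy, dims[2] / 2.0]), dimensions=dims)
    # majority foot label inside the final projections decides the side
    counts = {FOOT_LABELS[0]: 0, FOOT_LABELS[1]: 0}
    for cam in calibration:
        labels = masks.get(cam.camera_id)
        if labels is None:
            continue
        rect = _project_rect(cam, box.corners)
        if rect is None:
            continue
        u0, v0, u1, v1 = rect
        win = labels[v0:v1, u0:u1]
        counts[FOOT_LABELS[0]] += int((win == FOOT_LABELS[0]).sum())
        counts[FOOT_LABELS[1]] += int((win == FOOT_LABELS[1]).sum())
    box.foot_side = "left" if counts[FOOT_LABELS[0]] >= counts[FOOT_LABELS[1]] else "right"

    # centroid refinement: the blob centroid of the winning foot label in
    # each view pins the centre far more sharply than rect coverage
    side_label = FOOT_LABELS[0] if box.foot_side == "left" else FOOT_LABELS[1]
    observations = []
    for cam in calibration:
        labels = masks.get(cam.camera_id)
        if labels is None:
            continue
        rect = _project_rect(cam, box.corners, pad=3)
        if rect is None:
            continue
        u0, v0, u1, v1 = rect
        win = labels[v0:v1, u0:u1] == side_label
        n = win.sum()
        if n < 10:
            continue
        vs, us = np.nonzero(win)
        observations.append((cam, np.array([u0 + us.mean(), v0 + vs.mean()])))
    if len(observations) >= config.min_views:
        try:
            tri = triangulate_point(observations)
            # views where the blob centroid disagrees with the consensus
            # are partially occluded (shank, swing leg, sled); drop them
            # and re-triangulate on the clean views
            res = []
            for cam, uv in observations:
                uv_hat, _ = project_points(cam, tri.point[None, :])
                res.append(float(np.linalg.norm(uv_hat[0] - uv)))
            res = np.asarray(res)
            cut = max(3.0, 2.0 * float(np.median(res)))
            keep = [o for o, r in zip(observations, res) if r <= cut]
            if config.min_views <= len(keep) < len(observations):
                observations = keep
                tri = triangulate_point(observations)
            if not tri.ill_conditioned:
                centre = np.array([tri.point[0], tri.point[1], dims[2] / 2.0])
                # a convex body's silhouette centroid is not the projection
                # of its centre; estimate that perspective bias on the box
                # itself and subtract it
                model_obs = []
                for cam, _ in observations:
                    uv = _silhouette_centroid(cam, FootBox(centre=centre,
                                                           dimensions=dims))
                    if uv is not None:
                        model_obs.append((cam, uv))
                if len(model_obs) >= config.min_views:
                    tri_model = triangulate_point(model_obs)
                    bias = tri_model.point - centre
                    centre = centre - np.array([bias[0], bias[1], 0.0])
                box.centre = centre
        except GeometryError:
            pass
    return box


# ---------------------------------------------------------------------------
# slice profiles


def extract_slice_profiles(
    box: FootBox,
    image: np.ndarray,
    camera: CameraModel,
    n_slices: int = 8,
    pad_px: int = 6,
    rect: tuple[int, int, int, int] | None = None,
    mask_signal: bool = True,
    foot_label: int | None = None,
) -> SliceProfile:
    """Reduce the projected box region to per-slice 1D columns.

    ``mask_signal`` treats the image as a label mask and profiles the
    binary foot-label signal (the synthetic path); with False the raw
    image is profiled as grayscale intensity.  ``foot_label`` restricts
    the signal to one foot's label so the contralateral swing foot
    passing through end-on views cannot masquerade as stance-foot
    motion.  Passing a precomputed ``rect`` keeps the region identical
    across frames so tracked columns stay aligned.
    """
    if n_slices < 1:
        raise ValueError("n_slices must be >= 1")
    if rect is None:
        rect = _project_rect(camera, box.corners, pad=pad_px)
        if rect is None:
            raise OutOfViewError(f"box projects outside camera {camera.camera_id}")
    u0, v0, u1, v1 = rect
    win = image[v0:v1, u0:u1]
    if mask_signal and foot_label is not None:
        sig = (win == foot_label).astype(np.float32)
    elif mask_signal:
        sig = ((win == FOOT_LABELS[0]) | (win == FOOT_LABELS[1])).astype(np.float32)
    else:
        sig = win.astype(np.float32)
    grad = ndimage.sobel(sig, axis=0, mode="nearest")

    # heel -> toe ordering: compare the image-x of the two box end faces
    half = np.array([box.dimensions[0] / 2.0, 0.0, 0.0])
    ends = np.stack([box.centre - half, box.centre + half])
    x_cam = ends @ camera.rotation.T + camera.translation
    K = camera.intrinsic_matrix
    u_ends = K[0, 0] * x_cam[:, 0] / x_cam[:, 2] + K[0, 2]
    heel_left = u_ends[0] <= u_ends[1]

    width = sig.shape[1]
    edges = np.linspace(0, width, n_slices + 1).astype(int)
    cols_i, cols_g = [], []
    for k in range(n_slices):
        sl = slice(edges[k], max(edges[k + 1], edges[k] + 1))
        cols_i.append(sig[:, sl].mean(axis=1))
        cols_g.append(grad[:, sl].mean(axis=1))
    intensity = np.stack(cols_i)
    gradient = np.stack(cols_g)
    if not heel_left:
        intensity = intensity[::-1]
        gradient = gradient[::-1]
    return SliceProfile(intensity=intensity, gradient=gradient, rect=rect,
                        heel_to_toe=True)


def _pair_offsets(prev: SliceProfile, cur: SliceProfile, max_shift: int):
    """Per-slice vertical displacement from ``prev`` to ``cur`` (px).

    Positive values mean the content moved down the image.  The integer
    shift minimising the joint SSD of intensity and gradient columns is
    refined by a parabola fit; ties break toward the smaller magnitude.
    Slices whose match is unreliable — flat content, a shift clamped at
    the search boundary, or grossly mismatched content mass (the foot
    essentially appearing or vanishing rather than moving) — report 0
    with their flag set.
    """
    n_slices, H = prev.intensity.shape
    S = min(max_shift, H - 1)
    offsets = np.zeros(n_slices)
    unreliable = np.zeros(n_slices, bool)
    shifts = np.arange(-S, S + 1)
    # prefer small |shift| on exact ties
    order = np.argsort(np.abs(shifts), kind="stable")
    for k in range(n_slices):
        a = np.stack([prev.intensity[k], prev.gradient[k]], axis=1)  # (H, 2)
        b = np.stack([cur.intensity[k], cur.gradient[k]], axis=1)
        if a.std() < 1e-9 and b.std() < 1e-9:
            unreliable[k] = True
            continue
        mass_a = float(prev.intensity[k].sum())
        mass_b = float(cur.intensity[k].sum())
        if mass_a > 1e-9 and mass_b > 1e-9:
            ratio = mass_b / mass_a
            if ratio < 0.25 or ratio > 4.0:
                unreliable[k] = True
                continue
        elif (mass_a > 1e-9) != (mass_b > 1e-9):
            unreliable[k] = True
            continue
        pad = np.pad(a, ((S, S), (0, 0)), mode="edge")
        win = np.lib.stride_tricks.sliding_window_view(pad, (H, 2)).reshape(
            2 * S + 1, H, 2)
        # win[i] = a shifted by (i - S): b[r] vs a[r - d] with d = i - S
        ssd = np.mean((win[::-1] - b[None]) ** 2, axis=(1, 2))
        i = int(order[np.argmin(ssd[order])])
        if i == 0 or i == len(shifts) - 1:
            unreliable[k] = True  # clamped at the search boundary
            continue
        d = float(shifts[i])
        # parabolic subpixel refinement around the integer minimum
        y0, y1, y2 = ssd[i - 1], ssd[i], ssd[i + 1]
        denom = y0 - 2 * y1 + y2
        if denom > 1e-12:
            d = d + 0.5 * (y0 - y2) / denom
        offsets[k] = d
    return offsets, unreliable


def track_slices(
    profiles: dict[int, SliceProfile],
    start_frame: int,
    max_shift: int = 15,
):
    """Cumulative per-slice vertical offsets, accumulated outward from anchor.

    ``profiles`` maps frame index -> SliceProfile (all sharing one rect).
    Returns ``(frames, cum, flat)``: sorted frame indices, an (F, n_slices)
    array of displacements relative to ``start_frame``, and a flat-profile
    flag array.
    """
    frames = np.array(sorted(profiles))
    if start_frame not in profiles:
        raise ValueError("profile series must cover start_frame")
    n_slices = profiles[start_frame].intensity.shape[0]
    cum = np.zeros((len(frames), n_slices))
    flat = np.zeros((len(frames), n_slices), bool)
    i0 = int(np.flatnonzero(frames == start_frame)[0])
    for i in range(i0 + 1, len(frames)):
        d, fl = _pair_offsets(profiles[frames[i - 1]], profiles[frames[i]], max_shift)
        cum[i] = cum[i - 1] + d
        flat[i] = fl
    for i in range(i0 - 1, -1, -1):
        d, fl = _pair_offsets(profiles[frames[i + 1]], profiles[frames[i]], max_shift)
        cum[i] = cum[i + 1] + d
        flat[i] = fl
    return frames, cum, flat


# ---------------------------------------------------------------------------
# event detection


def _onset_from_crossing(f: int, y2: float, y1: float, forward: bool) -> float:
    """Movement-onset estimate from the threshold-bracketing displacements.

    ``y1``/``y2`` are |cumulative displacement| one frame before / at the
    first supra-threshold frame ``f``.  The displacement ramps from zero
    at the instant the foot starts moving, so extrapolating the ramp
    back to zero removes the threshold-crossing lag.  Clamped to at most
    three frames of extrapolation.
    """
    if y2 - y1 > 1e-9:
        back = y2 / (y2 - y1)
    else:
        back = 1.0
    back = min(back, 3.0)
    return f - back if forward else f + back


def _crossing_onset(frames, cum, slice_idx, start_frame, delta, forward: bool):
    """Onset estimate for one camera, or None if no crossing occurred."""
    sel = frames > start_frame if forward else frames < start_frame
    f = frames[sel]
    c = np.abs(cum[sel][:, slice_idx])
    if not forward:
        f, c = f[::-1], c[::-1]
    over = np.flatnonzero(c > delta)
    if over.size == 0:
        return None
    i = over[0]
    y1 = float(c[i - 1]) if i > 0 else 0.0
    return _onset_from_crossing(int(f[i]), float(c[i]), y1, forward)


def _median_toward(values, anchor: float) -> int:
    """Median of per-camera estimates, half-frame ties toward the anchor."""
    med = float(np.median(values))
    lo = math.floor(med)
    frac = med - lo
    if abs(frac - 0.5) < 1e-9:
        return lo + 1 if med < anchor else lo
    return lo + 1 if frac > 0.5 else lo


def detect_td_to(
    candidate: ContactCandidate,
    offsets_per_camera: dict[str, tuple[np.ndarray, np.ndarray]],
    fps: float,
    config: FootEventConfig | None = None,
    location: np.ndarray | None = None,
    foot_side: str = "unknown",
    end_slices: dict[str, tuple[int, int]] | None = None,
) -> ContactEvent:
    """Fuse per-camera slice displacements into a contact event.

    Per camera the toe-end slice (tracking forwards) and heel-end slice
    (tracking backwards) carry the event: the first cumulative vertical
    displacement beyond ``delta_px`` marks movement, and the displacement
    ramp is extrapolated back to zero to estimate the frame at which the
    slice *started* to move.  ``end_slices`` maps camera to (heel, toe)
    slice indices — the outermost slices that actually carry foot
    content; by default the first and last slice.  Onsets further than
    ``onset_window_s`` from the candidate's own first/last frame are
    rejected as unreliable (e.g. an occlusion edge sweeping across the
    stance foot fakes mid-stance motion in that view).  Cameras are
    fused by the median, half-frame ties rounding toward mid-stance;
    when no camera shows an acceptable crossing the candidate's
    first/last frames are used with a fallback flag.
    """
    config = config or FootEventConfig()
    anchor = candidate.peak_frame
    window = config.onset_window_s * fps
    tds, tos = [], []
    for cid, (frames, cum) in offsets_per_camera.items():
        heel_idx, toe_idx = (end_slices or {}).get(cid, (0, -1))
        on = _crossing_onset(frames, cum, toe_idx, anchor, config.delta_px, forward=True)
        if on is not None and abs(on - candidate.last_frame) <= window:
            tos.append(on)
        on = _crossing_onset(frames, cum, heel_idx, anchor, config.delta_px, forward=False)
        if on is not None and abs(on - candidate.first_frame) <= window:
            tds.append(on)
    flags = []
    if tds:
        td = _median_toward(tds, anchor)
    else:
        td = candidate.first_frame
        flags.append("td_fallback")
    if tos:
        to = _median_toward(tos, anchor)
    else:
        to = candidate.last_frame
        flags.append("to_fallback")
    if td >= to:
        td, to = candidate.first_frame, candidate.last_frame
        flags.append("degenerate_order_fallback")
    loc = np.array([candidate.location[0], candidate.location[1], 0.0])
    if location is not None:
        loc = np.array([location[0], location[1], 0.0])
    return ContactEvent(
        foot_side=foot_side, td_frame=td, to_frame=to,
        td_time=td / fps, to_time=to / fps, location=loc,
        source=candidate, flags=flags,
    )


# ---------------------------------------------------------------------------
# end-to-end refinement of one candidate


def refine_contact_event(
    candidate: ContactCandidate,
    sequence: MaskSequence,
    calibration: CalibrationSet,
    config: FootEventConfig | None = None,
) -> ContactEvent:
    """Run box fitting + slice tracking + event detection for one candidate.

    Frames are pulled from the sequence lazily, scanning outward from the
    mid-stance anchor until every usable camera has shown a displacement
    crossing (or the search window is exhausted).  Displacement here is
    measured by matching each frame's slice columns directly against the
    anchor profile rather than chaining frame-to-frame offsets: for a
    stationary stance both are zero, but direct matching does not let
    correlated segmentation-boundary jitter accumulate into spurious
    displacement.
    """
    config = config or FootEventConfig()
    fps = sequence.fps
    anchor = candidate.peak_frame
    masks_anchor = sequence.frames_at(anchor)
    box = fit_foot_box(candidate, masks_anchor, calibration, config)

    # views that resolve the foot: keep ~2 px per slice by shrinking the
    # slice count for distant views (minimum 3); cameras whose rect is
    # smaller than that — end-on, very far — yield meaningless matches
    # and are excluded
    rects = {}
    slices = {}
    for cam in calibration:
        rect = _project_rect(cam, box.corners, pad=config.pad_px)
        if rect is None:
            continue
        width, height = rect[2] - rect[0], rect[3] - rect[1]
        if width < 6 or height < 6:
            continue
        rects[cam.camera_id] = rect
        slices[cam.camera_id] = int(min(config.n_slices, max(3, width // 2)))

    side_label = (FOOT_LABELS[0] if box.foot_side == "left" else FOOT_LABELS[1])

    def profile(cid, labels):
        return extract_slice_profiles(
            box, labels, calibration[cid], n_slices=slices[cid],
            pad_px=config.pad_px, rect=rects[cid], foot_label=side_label)

    base = {cid: profile(cid, masks_anchor[cid]) for cid in rects}
    # outermost slices carrying foot content at the anchor: the "last
    # slice that displaces" at each end of the box
    ends = {}
    for cid, prof in list(base.items()):
        active = np.flatnonzero(prof.intensity.sum(axis=1) > 1e-6)
        if active.size == 0:
            del base[cid]
            del rects[cid]
            continue
        ends[cid] = (int(active[0]), int(active[-1]))
    search = int(round(config.search_s * fps))
    lo = max(candidate.first_frame - search, 0)
    hi = min(candidate.last_frame + search, sequence.n_frames - 1)

    tds, tos = [], []
    window = config.onset_window_s * fps
    for forward in (True, False):
        bound = candidate.last_frame if forward else candidate.first_frame
        sink = tos if forward else tds
        last_disp = {cid: 0.0 for cid in rects}
        fresh = {cid: True for cid in rects}
        provisional: dict[str, float] = {}
        pending = set(rects)
        rng = range(anchor + 1, hi + 1) if forward else range(anchor - 1, lo - 1, -1)
        for f in rng:
            if not pending:
                break
            for cid in list(pending):
                labels = sequence.frame(cid, f)
                cur = profile(cid, labels)
                d, junk = _pair_offsets(base[cid], cur, config.max_shift_px)
                slice_idx = ends[cid][1] if forward else ends[cid][0]
                y2 = abs(d[slice_idx])
                # implausibly large frame-to-frame change = a mismatch, not
                # motion; skip it and drop any unconfirmed crossing
                if junk[slice_idx] or abs(y2 - last_disp[cid]) > config.max_step_px:
                    provisional.pop(cid, None)
                    fresh[cid] = False
                    continue
                y1 = last_disp[cid]
                was_fresh = fresh[cid]
                last_disp[cid] = y2
                fresh[cid] = True
                if cid in provisional:
                    # a crossing counts once the next clean frame stays over
                    # the threshold; isolated spikes are discarded
                    onset = provisional.pop(cid)
                    if y2 > config.delta_px:
                        if abs(onset - bound) <= window:
                            sink.append(onset)
                        pending.discard(cid)
                    continue
                # onset extrapolation needs a measured previous frame, or
                # the slope (and hence the onset) is meaningless
                if y2 > config.delta_px and was_fresh:
                    provisional[cid] = _onset_from_crossing(f, y2, y1, forward)
        for cid, onset in provisional.items():
            if abs(onset - bound) <= window:
                sink.append(onset)

    flags = [] if not box.low_confidence else ["low_confidence_box"]
    if candidate.first_frame <= 1:
        flags.append("window_edge_start")  # stance began before capture
    if candidate.last_frame >= sequence.n_frames - 2:
        flags.append("window_edge_end")
    if tds:
        td = _median_toward(tds, anchor)
    else:
        td = candidate.first_frame
        flags.append("td_fallback")
    if tos:
        to = _median_toward(tos, anchor)
    else:
        to = candidate.last_frame
        flags.append("to_fallback")
    if td >= to:
        td, to = candidate.first_frame, candidate.last_frame
        flags.append("degenerate_order_fallback")
    return ContactEvent(
        foot_side=box.foot_side or "unknown",
        td_frame=td, to_frame=to, td_time=td / fps, to_time=to / fps,
        location=np.array([box.centre[0], box.centre[1], 0.0]),
        source=candidate, flags=flags,
    )
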