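"""Ground-plane occupancy mapping and approximate footfall detection.

The scene is divided into a horizontal grid of cells.  For each cell and
each probe height a small box volume (cell footprint x a thin height
band) is projected into every camera; the per-camera score is the
fraction of the projected region's pixels that are foreground, and the
cell's occupancy is the mean of those scores over the cameras that see
the region.  The mean (rather than a sum) keeps values in [0, 1] and
makes thresholds independent of camera count.

Projected probe regions are approximated by the axis-aligned bounding
rectangle of the eight projected corners, evaluated with a summed-area
table, which keeps a full-grid sweep tractable at 200 Hz.

The ground probe band is centred ``ground_offset`` above the physical
ground (default 0.025 m): raising the detection plane slightly avoids
partial occlusions by a low sled riding next to the feet.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .geometry import CalibrationSet
from .masks import MaskSequence


@dataclass(frozen=True)
class GridSpec:
    """Horizontal ground grid: origin (x0, y0), cell count and size."""

    origin: tuple[float, float] = (0.0, -1.0)
    shape: tuple[int, int] = (200, 40)  # (nx, ny)
    cell_size: float = 0.05

    def __post_init__(self):
        if self.cell_size <= 0:
            raise ValueError("cell_size must be positive")

    def cell_centre(self, ix, iy):
        x0, y0 = self.origin
        return np.array([x0 + (np.asarray(ix) + 0.5) * self.cell_size,
                         y0 + (np.asarray(iy) + 0.5) * self.cell_size]).T


@dataclass(frozen=True)
class OccupancyConfig:
    """Tunables of the footfall detector (defaults sized for sprinting feet)."""

    ground_offset: float = 0.025   # m, centre of the ground probe band
    knee_height: float = 0.5       # m
    body_height: float = 1.0       # m
    band: float = 0.05             # probe band thickness, m
    detection_threshold: float = 0.5
    verification_threshold: float = 0.3
    knee_radius: float = 0.5       # m, search radius for knee-height support
    body_radius: float = 1.0       # m
    min_duration: int = 5          # frames; shorter runs are flickers
    link_radius_m: float = 0.30    # peak-to-peak linking distance, metres
    link_max_gap: int = 3          # frames a run may skip (noise robustness)

    @property
    def heights(self) -> tuple[float, float, float]:
        return (self.ground_offset, self.knee_height, self.body_height)


@dataclass
class OccupancyMap:
    grid: GridSpec
    heights: tuple[float, ...]
    values: np.ndarray    # (n_heights, nx, ny) in [0, 1]
    coverage: np.ndarray  # (n_heights, nx, ny) viewing-camera counts

    @property
    def ground(self) -> np.ndarray:
        return self.values[0]


@dataclass
class ContactCandidate:
    """A linked run of verified ground-plane peaks: one approximate footfall."""

    cell: tuple[int, int]
    location: np.ndarray          # (x, y) m, occupancy-weighted at peak frame
    first_frame: int
    peak_frame: int
    last_frame: int
    peak_occupancy: float
    verified: bool = True
    flags: list[str] = field(default_factory=list)


class GridProjection:
    """Pre-projected probe rectangles: static per (calibration, grid, heights)."""

    def __init__(self, calibration: CalibrationSet, grid: GridSpec,
                 heights, band: float):
        self.calibration = calibration
        self.grid = grid
        self.heights = tuple(heights)
        self.band = band
        nx, ny = grid.shape
        x0, y0 = grid.origin
        xs = x0 + np.arange(nx + 1) * grid.cell_size
        ys = y0 + np.arange(ny + 1) * grid.cell_size
        XX, YY = np.meshgrid(xs, ys, indexing="ij")  # (nx+1, ny+1)
        self.rects = {}
        self.valid = {}
        self.areas = {}
        for cam in calibration:
            K, R, t = cam.intrinsic_matrix, cam.rotation, cam.translation
            w, h = cam.image_size
            u_layers, v_layers, ok_layers = [], [], []
            for zc in self.heights:
                for z in (zc - band / 2.0, zc + band / 2.0):
                    P = np.stack([XX, YY, np.full_like(XX, z)], axis=-1)
                    x_cam = P @ R.T + t
                    zz = x_cam[..., 2]
                    ok = zz > 1e-6
                    with np.errstate(divide="ignore", invalid="ignore"):
                        u = K[0, 0] * x_cam[..., 0] / zz + K[0, 2]
                        v = K[1, 1] * x_cam[..., 1] / zz + K[1, 2]
                    u_layers.append(u)
                    v_layers.append(v)
                    ok_layers.append(ok)
            u = np.stack(u_layers).reshape(len(self.heights), 2, nx + 1, ny + 1)
            v = np.stack(v_layers).reshape(len(self.heights), 2, nx + 1, ny + 1)
            ok = np.stack(ok_layers).reshape(len(self.heights), 2, nx + 1, ny + 1)

            def cellwise(a, op):
                corners = np.stack([
                    a[:, :, :-1, :-1], a[:, :, 1:, :-1],
                    a[:, :, :-1, 1:], a[:, :, 1:, 1:],
                ])
                return op(op(corners, axis=0), axis=1)

            umin = cellwise(u, np.min)
            umax = cellwise(u, np.max)
            vmin = cellwise(v, np.min)
            vmax = cellwise(v, np.max)
            all_ok = cellwise(ok.astype(float), np.min) > 0.5
            u0 = np.floor(umin).astype(np.int64)
            u1 = np.floor(umax).astype(np.int64) + 1
            v0 = np.floor(vmin).astype(np.int64)
            v1 = np.floor(vmax).astype(np.int64) + 1
            inside = all_ok & (u0 >= 0) & (v0 >= 0) & (u1 <= w) & (v1 <= h)
            u0c, u1c = np.clip(u0, 0, w), np.clip(u1, 0, w)
            v0c, v1c = np.clip(v0, 0, h), np.clip(v1, 0, h)
            self.rects[cam.camera_id] = (u0c, u1c, v0c, v1c)
            self.valid[cam.camera_id] = inside
            self.areas[cam.camera_id] = np.maximum((u1c - u0c) * (v1c - v0c), 1)


def _integral(fg: np.ndarray) -> np.ndarray:
    S = np.zeros((fg.shape[0] + 1, fg.shape[1] + 1), np.int64)
    np.cumsum(np.cumsum(fg, axis=0, dtype=np.int64), axis=1, out=S[1:, 1:])
    return S


class _BoxSums:
    """Summed-area queries restricted to the foreground bounding box.

    Rectangle sums outside the box are zero by construction, so the
    integral image only needs to cover the (small) foreground extent.
    """

    def __init__(self, fg: np.ndarray):
        rows = np.flatnonzero(fg.any(axis=1))
        if rows.size == 0:
            self.empty = True
            return
        self.empty = False
        cols = np.flatnonzero(fg.any(axis=0))
        self.r0, r1 = int(rows[0]), int(rows[-1]) + 1
        self.c0, c1 = int(cols[0]), int(cols[-1]) + 1
        self.S = _integral(fg[self.r0:r1, self.c0:c1])
        self.h = r1 - self.r0
        self.w = c1 - self.c0

    def rect_sums(self, u0, u1, v0, v1):
        if self.empty:
            return np.zeros(u0.shape, np.int64)
        a0 = np.clip(u0 - self.c0, 0, self.w)
        a1 = np.clip(u1 - self.c0, 0, self.w)
        b0 = np.clip(v0 - self.r0, 0, self.h)
        b1 = np.clip(v1 - self.r0, 0, self.h)
        S = self.S
        return S[b1, a1] - S[b0, a1] - S[b1, a0] + S[b0, a0]


def compute_occupancy_map(
    masks: dict[str, np.ndarray],
    calibration: CalibrationSet,
    grid: GridSpec,
    config: OccupancyConfig | None = None,
    projection: GridProjection | None = None,
) -> OccupancyMap:
    """Fuse one frame's per-camera masks into an occupancy map.

    ``masks`` maps camera_id to a label image; foreground is any nonzero
    label.  Cells seen by no camera score 0 (coverage 0).
    """
    config = config or OccupancyConfig()
    if projection is None:
        projection = GridProjection(calibration, grid, config.heights, config.band)
    nH = len(projection.heights)
    nx, ny = grid.shape
    acc = np.zeros((nH, nx, ny))
    cnt = np.zeros((nH, nx, ny), np.int32)
    for cam in calibration:
        cid = cam.camera_id
        if cid not in masks:
            continue
        fg = masks[cid] > 0
        box = _BoxSums(fg)
        u0, u1, v0, v1 = projection.rects[cid]
        sums = box.rect_sums(u0, u1, v0, v1)
        frac = sums / projection.areas[cid]
        valid = projection.valid[cid]
        acc[valid] += frac[valid]
        cnt[valid] += 1
    values = np.divide(acc, cnt, out=np.zeros_like(acc), where=cnt > 0)
    return OccupancyMap(grid=grid, heights=projection.heights,
                        values=values, coverage=cnt)


_EIGHT = np.ones((3, 3), bool)


def detect_ground_peaks(occ: OccupancyMap, threshold: float) -> list[tuple[int, int]]:
    """Local maxima of the ground layer at or above ``threshold``.

    Adjacent supra-threshold cells (8-connectivity) merge into a single
    peak at their maximum cell; plateau ties break toward smaller X then
    smaller Y grid index.
    """
    g = occ.ground
    labelled, n = ndimage.label(g >= threshold, structure=_EIGHT)
    peaks = []
    for comp in range(1, n + 1):
        idx = np.argwhere(labelled == comp)
        vals = g[idx[:, 0], idx[:, 1]]
        best = vals.max()
        ties = idx[vals >= best - 1e-12]
        order = np.lexsort((ties[:, 1], ties[:, 0]))
        peaks.append(tuple(int(v) for v in ties[order[0]]))
    peaks.sort()
    return peaks


def verify_peaks_at_heights(
    occ: OccupancyMap,
    ground_peaks: list[tuple[int, int]],
    config: OccupancyConfig | None = None,
) -> list[dict]:
    """Check knee- and body-height support near each ground peak.

    A peak is verified when occupancy at or above the verification
    threshold exists within ``knee_radius`` of it at knee height *and*
    within ``body_radius`` at body height.
    """
    config = config or OccupancyConfig()
    if occ.values.shape[0] < 3:
        raise ValueError("knee and body heights must be sampled for verification")
    nx, ny = occ.grid.shape
    out = []
    for (ix, iy) in ground_peaks:
        ok = True
        for layer, radius in ((1, config.knee_radius), (2, config.body_radius)):
            r_cells = int(np.ceil(radius / occ.grid.cell_size))
            x0, x1 = max(ix - r_cells, 0), min(ix + r_cells + 1, nx)
            y0, y1 = max(iy - r_cells, 0), min(iy + r_cells + 1, ny)
            window = occ.values[layer, x0:x1, y0:y1]
            jx, jy = np.meshgrid(np.arange(x0, x1), np.arange(y0, y1), indexing="ij")
            dist = np.hypot(jx - ix, jy - iy) * occ.grid.cell_size
            if not np.any((window >= config.verification_threshold)
                          & (dist <= radius)):
                ok = False
                break
        out.append({"cell": (ix, iy), "verified": ok,
                    "value": float(occ.ground[ix, iy])})
    return out


def _refined_location(occ: OccupancyMap, cell) -> np.ndarray:
    """Occupancy-weighted centroid over the 3x3 neighbourhood of a peak cell."""
    ix, iy = cell
    nx, ny = occ.grid.shape
    x0, x1 = max(ix - 1, 0), min(ix + 2, nx)
    y0, y1 = max(iy - 1, 0), min(iy + 2, ny)
    w = occ.ground[x0:x1, y0:y1]
    jx, jy = np.meshgrid(np.arange(x0, x1), np.arange(y0, y1), indexing="ij")
    centres = occ.grid.cell_centre(jx.ravel(), jy.ravel())
    tw = w.sum()
    if tw <= 0:
        return occ.grid.cell_centre(ix, iy)
    return (centres * w.ravel()[:, None]).sum(axis=0) / tw


class _Track:
    __slots__ = ("frames", "cells", "values", "locations")

    def __init__(self):
        self.frames, self.cells, self.values, self.locations = [], [], [], []


def contact_candidates_over_time(
    sequence: MaskSequence,
    calibration: CalibrationSet,
    grid: GridSpec,
    config: OccupancyConfig | None = None,
    frame_range: tuple[int, int] | None = None,
    on_frame=None,
) -> list[ContactCandidate]:
    """Link verified per-frame ground peaks into contact candidates.

    Peaks in consecutive frames within ``link_radius_m`` of each other
    (occupancy-weighted locations) belong to the same footfall — the
    argmax of a flat-topped foot blob wobbles across the foot between
    frames, so linking uses the stabler weighted location; runs shorter
    than ``min_duration`` frames are discarded as flickers.
    ``on_frame(index, occ, masks)`` lets a caller piggyback on the sweep
    (e.g. to harvest body-height peaks).
    """
    config = config or OccupancyConfig()
    projection = GridProjection(calibration, grid, config.heights, config.band)
    lo, hi = frame_range if frame_range else (0, sequence.n_frames)
    active: list[_Track] = []
    done: list[_Track] = []

    for f in range(lo, hi):
        masks = sequence.frames_at(f)
        occ = compute_occupancy_map(masks, calibration, grid, config, projection)
        if on_frame is not None:
            on_frame(f, occ, masks)
        peaks = detect_ground_peaks(occ, config.detection_threshold)
        verified = [p for p in verify_peaks_at_heights(occ, peaks, config)
                    if p["verified"]]
        for p in verified:
            p["location"] = _refined_location(occ, p["cell"])
        used = [False] * len(verified)
        still_active = []
        for tr in active:
            last = tr.locations[-1]
            hit = None
            for i, p in enumerate(verified):
                if used[i]:
                    continue
                if np.hypot(*(p["location"] - last)) <= config.link_radius_m:
                    hit = i
                    break
            if hit is not None:
                used[hit] = True
                p = verified[hit]
                tr.frames.append(f)
                tr.cells.append(p["cell"])
                tr.values.append(p["value"])
                tr.locations.append(p["location"])
                still_active.append(tr)
            elif f - tr.frames[-1] <= config.link_max_gap:
                still_active.append(tr)  # tolerate a short dropout
            else:
                done.append(tr)
        active = still_active
        for i, p in enumerate(verified):
            if used[i]:
                continue
            tr = _Track()
            tr.frames.append(f)
            tr.cells.append(p["cell"])
            tr.values.append(p["value"])
            tr.locations.append(p["location"])
            active.append(tr)
    done.extend(active)

    candidates = []
    for tr in done:
        if len(tr.frames) < config.min_duration:
            continue
        # anchor = centre of the (smoothed) occupancy maximum; smoothing
        # keeps per-frame segmentation noise from throwing the anchor to
        # a random stance frame
        vals = np.asarray(tr.values)
        w = min(5, len(vals))
        kernel = np.ones(w) / w
        smooth = np.convolve(vals, kernel, mode="same")
        best = smooth.max()
        plateau = np.flatnonzero(smooth >= best - 1e-9)
        k = int(plateau[len(plateau) // 2])
        candidates.append(
            ContactCandidate(
                cell=tr.cells[k],
                location=np.asarray(tr.locations[k]),
                first_frame=tr.frames[0],
                peak_frame=tr.frames[k],
                last_frame=tr.frames[-1],
                peak_occupancy=float(best),
            )
        )
    candidates.sort(key=lambda c: (c.first_frame, c.location[0]))
    return candidates
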