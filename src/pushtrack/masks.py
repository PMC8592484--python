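"""Part-labelled segmentation masks: containers, part codes and PNG I/O.

Masks stand in for the output of a person/part-segmentation network: one
8-bit single-channel image per camera per frame, each pixel holding a
body-part code (0 = background).  Foreground is any nonzero label; the
sled is deliberately never labelled as foreground.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass
from pathlib import Path

import imageio.v3 as iio
import numpy as np

# Enumerated part codes (value 0 reserved for background).
PART_CODES = {
    "background": 0,
    "head": 1,
    "torso": 2,
    "upper_arm_left": 3,
    "upper_arm_right": 4,
    "lower_arm_left": 5,
    "lower_arm_right": 6,
    "hand_left": 7,
    "hand_right": 8,
    "thigh_left": 9,
    "thigh_right": 10,
    "shank_left": 11,
    "shank_right": 12,
    "foot_left": 13,
    "foot_right": 14,
}
CODE_NAMES = {v: k for k, v in PART_CODES.items()}
FOOT_LABELS = (PART_CODES["foot_left"], PART_CODES["foot_right"])


@dataclass(frozen=True)
class MaskFrame:
    """One camera's label image for one frame."""

    camera_id: str
    frame_index: int
    labels: np.ndarray  # (H, W) uint8 part codes

    @property
    def foreground(self) -> np.ndarray:
        return self.labels > 0


class MaskSequence:
    """Per-camera, per-frame label images behind a uniform access interface.

    Concrete sources (in-memory arrays, a PNG directory tree, or a lazy
    synthetic renderer) subclass this; the pipeline only ever calls
    ``frame(camera_id, index)`` so long sequences never need to be held
    in memory at once.
    """

    def __init__(self, camera_ids: list[str], n_frames: int, fps: float = 200.0):
        if fps <= 0:
            raise ValueError("fps must be positive")
        self.camera_ids = list(camera_ids)
        self.n_frames = int(n_frames)
        self.fps = float(fps)

    def frame(self, camera_id: str, index: int) -> np.ndarray:
        raise NotImplementedError

    def frames_at(self, index: int) -> dict[str, np.ndarray]:
        """All cameras' label images at one frame index."""
        return {cid: self.frame(cid, index) for cid in self.camera_ids}


class ArrayMaskSequence(MaskSequence):
    """Masks held in memory as {camera_id: (T, H, W) uint8 array}."""

    def __init__(self, arrays: dict[str, np.ndarray], fps: float = 200.0):
        counts = {cid: arr.shape[0] for cid, arr in arrays.items()}
        if len(set(counts.values())) > 1:
            raise ValueError(f"cameras disagree on frame count: {counts}")
        n = next(iter(counts.values())) if counts else 0
        super().__init__(list(arrays), n, fps)
        self._arrays = {cid: np.asarray(a, np.uint8) for cid, a in arrays.items()}

    def frame(self, camera_id: str, index: int) -> np.ndarray:
        return self._arrays[camera_id][index]


_FRAME_RE = re.compile(r"frame(\d+)\.png$")


class DirectoryMaskSequence(MaskSequence):
    """Masks stored on disk as ``cam<id>/frame<%06d>.png`` trees."""

    def __init__(self, root: Path, fps: float = 200.0):
        root = Path(root)
        cam_dirs = sorted(p for p in root.iterdir() if p.is_dir() and p.name.startswith("cam"))
        if not cam_dirs:
            raise FileNotFoundError(f"no cam*/ directories under {root}")
        self._paths: dict[str, dict[int, Path]] = {}
        for d in cam_dirs:
            cid = d.name[3:]
            frames = {}
            for p in d.glob("frame*.png"):
                m = _FRAME_RE.search(p.name)
                if m:
                    frames[int(m.group(1))] = p
            self._paths[cid] = frames
        counts = {cid: len(f) for cid, f in self._paths.items()}
        n = max(counts.values())
        meta = root / "masks.json"
        if meta.exists():
            with open(meta) as fh:
                fps = float(json.load(fh).get("fps", fps))
        super().__init__(sorted(self._paths), n, fps)
        self.root = root

    def frame(self, camera_id: str, index: int) -> np.ndarray:
        return np.asarray(iio.imread(self._paths[camera_id][index]))

    def frame_indices(self, camera_id: str) -> list[int]:
        return sorted(self._paths[camera_id])


def write_mask_sequence(seq: MaskSequence, root: Path) -> None:
    """Write a sequence as PNG trees plus a JSON sidecar with fps/part codes."""
    root = Path(root)
    root.mkdir(parents=True, exist_ok=True)
    for cid in seq.camera_ids:
        d = root / f"cam{cid}"
        d.mkdir(exist_ok=True)
        for i in range(seq.n_frames):
            iio.imwrite(d / f"frame{i:06d}.png", seq.frame(cid, i).astype(np.uint8))
    with open(root / "masks.json", "w") as fh:
        json.dump({"fps": seq.fps, "part_codes": PART_CODES}, fh, indent=1)


def part_bbox(labels: np.ndarray, code: int):
    """Tight inclusive bounding box (u0, v0, u1, v1) of a part label, or None."""
    mask = labels == code
    cols = mask.any(axis=0)
    if not cols.any():
        return None
    rows = mask.any(axis=1)
    u = np.flatnonzero(cols)
    v = np.flatnonzero(rows)
    return int(u[0]), int(v[0]), int(u[-1]), int(v[-1])
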