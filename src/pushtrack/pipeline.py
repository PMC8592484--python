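"""End-to-end workflow: occupancy -> events -> tracking -> steps -> stats.

A scene directory holds a calibration JSON, per-camera PNG mask trees,
optionally sled-corner detections (CNN stand-in) and optionally a
per-step criterion CSV; the pipeline turns it into contact events, step
characteristics, smoothed athlete/sled trajectories and (when a
criterion is present) a Bland-Altman agreement report.
"""

from __future__ import annotations

import dataclasses
import json
import os
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import com_tracking as ct
from .agreement import bland_altman
from .foot_events import ContactEvent, FootEventConfig, refine_contact_event
from .geometry import CalibrationSet, CalibrationSchemaError, load_calibration
from .masks import CODE_NAMES, PART_CODES, DirectoryMaskSequence, MaskSequence
from .occupancy import (
    ContactCandidate,
    GridSpec,
    OccupancyConfig,
    contact_candidates_over_time,
    detect_ground_peaks,
)
from .step_metrics import (
    Step,
    StepSequenceError,
    assign_leg_roles,
    attach_step_velocities,
    pair_events_to_steps,
    steps_to_frame,
)

DEFAULT_SLED_TEMPLATE = np.array(
    [[-0.45, -0.25, 0.0], [0.45, -0.25, 0.0], [0.45, 0.25, 0.0], [-0.45, 0.25, 0.0]]
)


@dataclass(frozen=True)
class StatsConfig:
    n_boot: int = 5000
    n_perm: int = 5000
    seed: int = 0


@dataclass(frozen=True)
class PipelineConfig:
    """Fully resolved configuration; one document drives every stage."""

    grid: GridSpec = field(default_factory=GridSpec)
    occupancy: OccupancyConfig = field(default_factory=OccupancyConfig)
    foot: FootEventConfig = field(default_factory=FootEventConfig)
    kalman: ct.KalmanConfig = field(default_factory=ct.KalmanConfig)
    stats: StatsConfig = field(default_factory=StatsConfig)
    com_weights: tuple[float, float] = (0.14, 0.86)
    sled_side: str | None = None
    sled_corner_confidence: float = 0.5
    body_peak_threshold: float = 0.3
    activity: str = "push"

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _build_dataclass(cls, doc: dict, path: str):
    names = {f.name: f for f in dataclasses.fields(cls)}
    unknown = set(doc) - set(names)
    if unknown:
        raise ValueError(f"unknown config key(s) {sorted(unknown)} under '{path}'")
    nested = {
        "grid": GridSpec, "occupancy": OccupancyConfig,
        "foot": FootEventConfig, "kalman": ct.KalmanConfig,
        "stats": StatsConfig,
    }
    kwargs = {}
    for key, value in doc.items():
        if isinstance(value, dict) and key in nested:
            kwargs[key] = _build_dataclass(nested[key], value, f"{path}.{key}")
            continue
        if isinstance(value, list):
            value = tuple(value)
        kwargs[key] = value
    return cls(**kwargs)


def config_from_dict(doc: dict) -> PipelineConfig:
    """Strict construction: unknown keys are rejected with their path."""
    return _build_dataclass(PipelineConfig, doc or {}, "config")


def load_config(path) -> PipelineConfig:
    with open(path) as fh:
        return config_from_dict(yaml.safe_load(fh) or {})


# ---------------------------------------------------------------------------
# scene inputs


@dataclass
class SceneInputs:
    masks: MaskSequence
    calibration: CalibrationSet
    sled_detections: pd.DataFrame | None = None
    criterion: pd.DataFrame | None = None

    @classmethod
    def from_directory(cls, scene_dir) -> "SceneInputs":
        scene_dir = Path(scene_dir)
        calib_path = scene_dir / "calibration.json"
        if not calib_path.exists():
            raise FileNotFoundError(f"missing input: {calib_path}")
        calibration = load_calibration(calib_path)
        masks = DirectoryMaskSequence(scene_dir)
        sled = None
        sled_path = scene_dir / "sled_detections.csv"
        if sled_path.exists():
            sled = pd.read_csv(sled_path, dtype={"camera_id": str})
        criterion = None
        crit_path = scene_dir / "criterion.csv"
        if crit_path.exists():
            criterion = pd.read_csv(crit_path)
        return cls(masks=masks, calibration=calibration,
                   sled_detections=sled, criterion=criterion)


@dataclass
class PipelineResult:
    candidates: list[ContactCandidate]
    events: list[ContactEvent]
    steps: list[Step]
    steps_frame: pd.DataFrame
    com_trajectory: ct.Trajectory | None
    sled_trajectory: ct.Trajectory | None
    agreement: pd.DataFrame | None
    log: dict


# ---------------------------------------------------------------------------
# stages


def sweep_scene(scene: SceneInputs, config: PipelineConfig):
    """Single pass over all frames: candidates + per-frame part boxes/peaks."""
    part_frames: dict[str, list[dict]] = {"head": [], "torso": []}
    body_peaks: list[list[np.ndarray]] = []

    def on_frame(f, occ, masks):
        peaks = []
        if occ.values.shape[0] >= 3:
            body_layer = occ.values[2]
            for (ix, iy) in _layer_peaks(body_layer, config.body_peak_threshold):
                peaks.append(occ.grid.cell_centre(ix, iy))
        body_peaks.append(peaks)
        for part in ("head", "torso"):
            code = PART_CODES[part]
            boxes = {}
            for cid, labels in masks.items():
                b = ct.part_boxes_2d(labels, code, part)
                if b is not None:
                    boxes[cid] = b
            part_frames[part].append(boxes)

    candidates = contact_candidates_over_time(
        scene.masks, scene.calibration, config.grid, config.occupancy,
        on_frame=on_frame)
    return candidates, part_frames, body_peaks


def _layer_peaks(layer: np.ndarray, threshold: float):
    from .occupancy import OccupancyMap

    dummy = OccupancyMap(grid=GridSpec(shape=layer.shape), heights=(0.0,),
                         values=layer[None], coverage=np.ones_like(layer[None]))
    return detect_ground_peaks(dummy, threshold)


def detect_events(scene: SceneInputs, config: PipelineConfig,
                  candidates: list[ContactCandidate]) -> list[ContactEvent]:
    events = []
    for cand in candidates:
        ev = refine_contact_event(cand, scene.masks, scene.calibration, config.foot)
        events.append(ev)
    return events


def track_athlete(scene: SceneInputs, config: PipelineConfig,
                  part_frames, body_peaks) -> ct.Trajectory | None:
    fps = scene.masks.fps
    series = {}
    for part in ("head", "torso"):
        pos, valid = ct.track_body_part(
            part_frames[part], scene.calibration, part,
            body_peaks_per_frame=body_peaks)
        series[part] = (pos, valid)
    com, valid, _ = ct.com_from_boxes(
        series["head"][0], series["head"][1],
        series["torso"][0], series["torso"][1], weights=config.com_weights)
    if valid.sum() < 2:
        return None
    return ct.build_trajectory(com, valid, fps, "athlete_com", config.kalman)


def track_sled(scene: SceneInputs, config: PipelineConfig,
               template: np.ndarray | None = None) -> ct.Trajectory | None:
    if scene.sled_detections is None or scene.sled_detections.empty:
        return None
    fps = scene.masks.fps
    n = scene.masks.n_frames
    model = ct.SledModel(template_corners=(
        DEFAULT_SLED_TEMPLATE if template is None else template))
    pos = np.full((n, 3), np.nan)
    valid = np.zeros(n, bool)
    for f, group in scene.sled_detections.groupby("frame"):
        f = int(f)
        if f < 0 or f >= n:
            continue
        obs = {}
        for _, row in group.iterrows():
            obs.setdefault(int(row.corner_id), []).append(
                (str(row.camera_id), (row.u_px, row.v_px), float(row.confidence)))
        pose = ct.fit_sled_pose(obs, scene.calibration, model,
                                config.sled_corner_confidence)
        if pose is not None:
            pos[f] = pose.centroid
            valid[f] = True
    if valid.sum() < 2:
        return None
    return ct.build_trajectory(pos, valid, fps, "sled", config.kalman)


def compute_steps(events: list[ContactEvent], config: PipelineConfig,
                  com: ct.Trajectory | None, sled: ct.Trajectory | None,
                  log: dict) -> list[Step]:
    drop = {"td_fallback", "to_fallback", "window_edge_start", "window_edge_end"}
    usable = [e for e in events if not drop & set(e.flags)]
    log["events_dropped_fallback"] = len(events) - len(usable)
    try:
        steps = pair_events_to_steps(usable)
    except StepSequenceError as exc:
        log["step_sequence_error"] = str(exc)
        # salvage: keep the longest alternating, non-overlapping prefix scan
        steps = []
        kept: list[ContactEvent] = []
        for e in sorted(usable, key=lambda e: e.td_time):
            if kept and (kept[-1].foot_side == e.foot_side
                         or e.td_time < kept[-1].to_time):
                continue
            kept.append(e)
        steps = pair_events_to_steps(kept)
    attach_step_velocities(steps, com, sled)
    assign_leg_roles(steps, config.sled_side, config.activity)
    return steps


def compute_agreement(steps_frame: pd.DataFrame,
                      criterion: pd.DataFrame) -> pd.DataFrame:
    """Bland-Altman rows for every variable shared with the criterion table."""
    rows = []
    merged = steps_frame.merge(criterion, on="step_index",
                               suffixes=("", "_crit"))
    for col in ("gct_s", "ft_s", "st_s", "sl_m", "sf_hz", "sv_ms",
                "com_v_ms", "sled_v_ms"):
        crit_col = f"{col}_crit"
        if crit_col not in merged.columns or col not in merged.columns:
            continue
        sub = merged[[col, crit_col]].dropna()
        if len(sub) < 2:
            continue
        res = bland_altman(sub[col].to_numpy(), sub[crit_col].to_numpy())
        rows.append({
            "variable": col, "bias": res.bias, "sd": res.sd,
            "loa_lower": res.loa_lower, "loa_upper": res.loa_upper,
            "r_squared": res.r_squared, "n": res.n,
        })
    return pd.DataFrame(rows)


def run_pipeline(scene: SceneInputs, config: PipelineConfig | None = None,
                 trial_id: str = "trial", athlete_id: str = "") -> PipelineResult:
    config = config or PipelineConfig()
    log: dict = {"n_frames": scene.masks.n_frames, "fps": scene.masks.fps,
                 "n_cameras": len(scene.calibration)}
    candidates, part_frames, body_peaks = sweep_scene(scene, config)
    log["n_candidates"] = len(candidates)
    events = detect_events(scene, config, candidates)
    log["n_events"] = len(events)
    com = track_athlete(scene, config, part_frames, body_peaks)
    sled = track_sled(scene, config)
    log["com_tracked"] = com is not None
    log["sled_tracked"] = sled is not None
    steps = compute_steps(events, config, com, sled, log)
    log["n_steps"] = len(steps)
    frame = steps_to_frame(steps, trial_id=trial_id, athlete_id=athlete_id,
                           activity=config.activity)
    agreement = None
    if scene.criterion is not None and not frame.empty:
        agreement = compute_agreement(frame, scene.criterion)
        log["agreement_rows"] = len(agreement)
    else:
        log["agreement"] = "skipped (no criterion data)"
    return PipelineResult(candidates=candidates, events=events, steps=steps,
                          steps_frame=frame, com_trajectory=com,
                          sled_trajectory=sled, agreement=agreement, log=log)


# ---------------------------------------------------------------------------
# persistence


def _atomic_write(path: Path, writer):
    tmp = path.with_suffix(path.suffix + ".tmp")
    writer(tmp)
    os.replace(tmp, path)


def events_to_frame(events: list[ContactEvent], trial_id: str = "trial"):
    rows = []
    for e in events:
        rows.append({
            "trial_id": trial_id, "foot_side": e.foot_side,
            "td_frame": e.td_frame, "to_frame": e.to_frame,
            "td_time_s": e.td_time, "to_time_s": e.to_time,
            "x_m": e.location[0], "y_m": e.location[1], "z_m": e.location[2],
            "flags": ";".join(e.flags),
        })
    return pd.DataFrame(rows)


def trajectory_to_frame(traj: ct.Trajectory) -> pd.DataFrame:
    n = len(traj.times)
    return pd.DataFrame({
        "frame": np.arange(n), "time_s": traj.times,
        "x": traj.positions[:, 0], "y": traj.positions[:, 1],
        "z": traj.positions[:, 2],
        "vx": traj.velocities[:, 0], "vy": traj.velocities[:, 1],
        "vz": traj.velocities[:, 2],
        "valid": traj.valid.astype(int), "label": traj.label,
    })


def write_outputs(result: PipelineResult, out_dir, config: PipelineConfig,
                  trial_id: str = "trial") -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    _atomic_write(out / "events.csv",
                  lambda p: events_to_frame(result.events, trial_id).to_csv(p, index=False))
    _atomic_write(out / "steps.csv",
                  lambda p: result.steps_frame.to_csv(p, index=False))
    for traj in (result.com_trajectory, result.sled_trajectory):
        if traj is not None:
            _atomic_write(out / f"trajectory_{traj.label}.csv",
                          lambda p, t=traj: trajectory_to_frame(t).to_csv(p, index=False))
    if result.agreement is not None:
        _atomic_write(out / "agreement.csv",
                      lambda p: result.agreement.to_csv(p, index=False))
    _atomic_write(out / "config_resolved.yaml",
                  lambda p: Path(p).write_text(yaml.safe_dump(config.to_dict())))
    _atomic_write(out / "log.json",
                  lambda p: Path(p).write_text(json.dumps(result.log, indent=1)))


# ---------------------------------------------------------------------------
# validation


def validate_inputs(scene_dir) -> dict:
    """Machine-readable consistency report for a scene directory."""
    scene_dir = Path(scene_dir)
    findings: list[dict] = []

    calib = None
    calib_path = scene_dir / "calibration.json"
    if not calib_path.exists():
        findings.append({"severity": "error", "what": "missing calibration.json"})
    else:
        try:
            calib = load_calibration(calib_path)
        except CalibrationSchemaError as exc:
            findings.append({"severity": "error",
                             "what": f"calibration schema: {exc}"})

    try:
        seq = DirectoryMaskSequence(scene_dir)
    except FileNotFoundError as exc:
        findings.append({"severity": "error", "what": str(exc)})
        return {"findings": findings, "ok": False}

    counts = {cid: len(seq.frame_indices(cid)) for cid in seq.camera_ids}
    if len(set(counts.values())) > 1:
        findings.append({"severity": "error",
                         "what": "cameras disagree on frame count",
                         "counts": counts})
    for cid in seq.camera_ids:
        idx = seq.frame_indices(cid)
        if idx and idx != list(range(idx[0], idx[0] + len(idx))):
            findings.append({"severity": "error",
                             "what": f"camera {cid}: frame indices not contiguous"})
        elif idx and idx[0] != 0:
            findings.append({"severity": "warning",
                             "what": f"camera {cid}: frames start at {idx[0]}, not 0"})
    if calib is not None:
        missing = set(calib.camera_ids) - set(seq.camera_ids)
        if missing:
            findings.append({"severity": "warning",
                             "what": f"no masks for calibrated camera(s) {sorted(missing)}"})
    # label codes of the first frame of each camera
    known = set(CODE_NAMES)
    for cid in seq.camera_ids:
        idx = seq.frame_indices(cid)
        if not idx:
            continue
        codes = set(np.unique(seq.frame(cid, idx[0])).tolist())
        bad = codes - known
        if bad:
            findings.append({"severity": "error",
                             "what": f"camera {cid}: unknown label code(s) {sorted(bad)}"})
    return {"findings": findings,
            "ok": not any(f["severity"] == "error" for f in findings)}
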