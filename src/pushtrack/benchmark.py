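"""Simulation-study harness: pipeline accuracy against synthetic truth.

Because the capture volume is ~10 m, one trial holds only a handful of
steps; the suite therefore simulates several pushing trials entering the
volume at different phases of the sprint acceleration (emulating
staggered starts) and pools the per-step errors: touchdown/toe-off
timing (frames), step length (m) and step-averaged athlete CoM and sled
velocities (m/s), each compared with the generator's analytic truth.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .pipeline import PipelineConfig, SceneInputs, run_pipeline
from .synthetic import (
    GaitParams,
    NoiseSpec,
    SledSpec,
    corrupt_masks,
    duration_for_distance,
    render_masks,
    simulate_gait,
)

DEFAULT_OFFSETS = (0.6, 0.9, 1.4, 2.0, 3.0)


@dataclass
class SuiteResult:
    steps: pd.DataFrame       # one row per matched detected step
    n_trials: int
    n_frames_total: int
    emitted: list = None      # per trial: (Step list, ContactEvent list)

    @property
    def n_steps(self) -> int:
        return len(self.steps)

    def summary(self) -> dict:
        s = self.steps
        out = {"n_steps": int(len(s))}
        if len(s) == 0:
            return out
        out["td_err_max_frames"] = float(s.td_err_frames.abs().max())
        out["to_err_max_frames"] = float(s.to_err_frames.abs().max())
        out["td_err_mean_frames"] = float(s.td_err_frames.mean())
        out["to_err_mean_frames"] = float(s.to_err_frames.mean())
        sl = s.sl_err_m.dropna()
        if len(sl) >= 2:
            out["sl_err_mean_m"] = float(sl.mean())
            out["sl_err_sd_m"] = float(sl.std(ddof=1))
        com = s.com_vel_err_ms.dropna()
        if len(com) >= 2:
            out["com_vel_err_mean_ms"] = float(com.mean())
            out["com_vel_err_sd_ms"] = float(com.std(ddof=1))
        sled = s.sled_vel_err_ms.dropna()
        if len(sled) >= 2:
            out["sled_vel_err_mean_ms"] = float(sled.mean())
            out["sled_vel_err_sd_ms"] = float(sled.std(ddof=1))
        return out


def run_push_trial(
    start_offset: float,
    calibration,
    noise: NoiseSpec | None = None,
    seed: int = 0,
    fps: float = 200.0,
    distance: float = 8.0,
    max_duration: float = 2.2,
    return_result: bool = False,
):
    """One pushing trial through the volume; per-step errors vs truth."""
    params = GaitParams(sled=SledSpec(), start_offset=start_offset, seed=seed)
    duration = min(duration_for_distance(params, distance), max_duration)
    truth = simulate_gait(params, duration, fps)
    masks, detections = render_masks(truth, calibration)
    if noise is not None and not noise.is_identity:
        masks = corrupt_masks(masks, noise, seed)
    scene = SceneInputs(masks=masks, calibration=calibration,
                        sled_detections=detections)
    result = run_pipeline(scene, PipelineConfig(sled_side="right"))

    contacts = truth.contacts
    # match detected events to truth contacts by stance location
    matches = {}
    for ev in result.events:
        if {"td_fallback", "to_fallback", "window_edge_start",
                "window_edge_end"} & set(ev.flags):
            continue
        i = int((contacts.x - ev.location[0]).abs().argmin())
        if abs(contacts.x.iloc[i] - ev.location[0]) > 0.4:
            continue
        tc = contacts.iloc[i]
        # only stances entirely inside the capture window are comparable
        if tc["td_frame"] <= 3 or tc["to_frame"] >= truth.n_frames - 4:
            continue
        matches[i] = (ev, tc)

    rows = []
    for i in sorted(matches):
        ev, tc = matches[i]
        row = {
            "trial_offset": start_offset,
            "foot": ev.foot_side,
            "td_err_frames": ev.td_frame - tc["td_frame"],
            "to_err_frames": ev.to_frame - tc["to_frame"],
            "x_err_m": ev.location[0] - tc["x"],
            "sl_err_m": np.nan,
            "com_vel_err_ms": np.nan,
            "sled_vel_err_ms": np.nan,
        }
        if i + 1 in matches:
            ev2, tc2 = matches[i + 1]
            row["sl_err_m"] = ((ev2.location[0] - ev.location[0])
                               - (tc2["x"] - tc["x"]))
            # step-averaged velocities over the detected step window,
            # against truth averaged over the true step window
            sel = ((truth.times >= tc["td_time"])
                   & (truth.times < tc2["td_time"]))
            true_v = float(truth.com_vel[sel, 0].mean())
            for step in result.steps:
                if abs(step.td_time - ev.td_time) < 1e-9:
                    if step.com_step_velocity is not None:
                        row["com_vel_err_ms"] = step.com_step_velocity - true_v
                    if step.sled_step_velocity is not None:
                        row["sled_vel_err_ms"] = step.sled_step_velocity - true_v
                    break
        row["n_frames"] = truth.n_frames
        rows.append(row)
    df = pd.DataFrame(rows)
    if return_result:
        return df, result
    return df


def run_push_suite(
    seed: int = 0,
    offsets=DEFAULT_OFFSETS,
    noise: NoiseSpec | None = None,
    fps: float = 200.0,
    n_cameras: int = 9,
) -> SuiteResult:
    """Run the multi-trial pushing suite and pool per-step errors."""
    from .synthetic import make_camera_ring

    calibration = make_camera_ring(n=n_cameras)
    frames = []
    emitted = []
    total = 0
    for k, off in enumerate(offsets):
        df, result = run_push_trial(off, calibration, noise=noise,
                                    seed=seed * 1009 + k, fps=fps,
                                    return_result=True)
        emitted.append((result.steps, result.events))
        if not df.empty:
            total += int(df.n_frames.iloc[0])
            frames.append(df.drop(columns="n_frames"))
    steps = (pd.concat(frames, ignore_index=True)
             if frames else pd.DataFrame())
    return SuiteResult(steps=steps, n_trials=len(offsets),
                       n_frames_total=total, emitted=emitted)


def bca_coverage_simulation(n_datasets: int = 1000, n: int = 12,
                            n_boot: int = 2000, seed: int = 0) -> float:
    """Empirical coverage of the 95% BCa interval for a paired mean.

    Gaussian paired data with a known mean difference; returns the
    fraction of datasets whose interval covers the true value.
    """
    from .agreement import bootstrap_bca_ci

    rng = np.random.default_rng(seed)
    true_delta = 0.4
    stat = lambda x, y: float(np.mean(x - y))
    hits = 0
    for i in range(n_datasets):
        b = rng.normal(0.0, 1.0, n)
        a = b + rng.normal(true_delta, 0.8, n)
        lo, hi, _ = bootstrap_bca_ci(a, b, statistic=stat, n_boot=n_boot,
                                     seed=int(rng.integers(2**31)))
        if lo <= true_delta <= hi:
            hits += 1
    return hits / n_datasets
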