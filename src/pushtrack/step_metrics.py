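"""Step characteristics from contact events and mass-centre trajectories.

A step runs from the touchdown of one foot to the touchdown of the
contralateral foot.  Ground contact time (GCT) is the leading foot's
stance duration, flight time (FT) the gap to the next touchdown, step
time ST = GCT + FT, step length SL the travel-axis (world X) distance
between the two touchdown locations, step frequency SF = 1/ST and step
velocity SV = SL/ST — identities that hold exactly by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .com_tracking import Trajectory
from .foot_events import ContactEvent


class StepSequenceError(ValueError):
    """Events do not alternate feet or overlap in time."""


@dataclass
class Step:
    index: int
    leading_foot: str
    td_time: float
    next_td_time: float
    to_time: float
    gct: float
    ft: float
    st: float
    sl: float
    sf: float
    sv: float
    leg_role: str = "unassigned"
    com_step_velocity: float | None = None
    sled_step_velocity: float | None = None
    flags: list[str] = field(default_factory=list)


def pair_events_to_steps(events: list[ContactEvent]) -> list[Step]:
    """Pair chronologically sorted alternating contacts into steps.

    Consecutive same-foot events or overlapping stances (next touchdown
    before the current toe-off) raise ``StepSequenceError`` naming the
    offending pair.  Fewer than two events yield no steps.
    """
    if len(events) < 2:
        return []
    evs = sorted(events, key=lambda e: e.td_time)
    steps = []
    for i, (a, b) in enumerate(zip(evs, evs[1:])):
        if a.foot_side == b.foot_side:
            raise StepSequenceError(
                f"events {i} and {i + 1} are both {a.foot_side}-footed")
        if b.td_time < a.to_time:
            raise StepSequenceError(
                f"event {i + 1} touches down (t={b.td_time:.3f}) before event "
                f"{i} toes off (t={a.to_time:.3f})")
        gct = a.to_time - a.td_time
        st = b.td_time - a.td_time
        sl = b.location[0] - a.location[0]
        steps.append(
            Step(
                index=i, leading_foot=a.foot_side,
                td_time=a.td_time, next_td_time=b.td_time, to_time=a.to_time,
                gct=gct, ft=st - gct, st=st, sl=sl, sf=1.0 / st, sv=sl / st,
            )
        )
    return steps


def step_averaged_velocity(step: Step, trajectory: Trajectory) -> float | None:
    """Mean valid X velocity over [td_i, td_{i+1}); None if uncovered."""
    t = trajectory.times
    sel = (t >= step.td_time) & (t < step.next_td_time) & trajectory.valid
    sel &= np.isfinite(trajectory.velocities[:, 0])
    if not sel.any():
        step.flags.append(f"no_velocity_samples[{trajectory.label}]")
        return None
    return float(trajectory.velocities[sel, 0].mean())


def attach_step_velocities(steps: list[Step], com: Trajectory | None,
                           sled: Trajectory | None = None) -> None:
    for s in steps:
        if com is not None:
            s.com_step_velocity = step_averaged_velocity(s, com)
        if sled is not None:
            s.sled_step_velocity = step_averaged_velocity(s, sled)


def assign_leg_roles(steps: list[Step], side_of_sled: str | None,
                     activity: str = "push") -> list[Step]:
    """Label steps inside (sled-adjacent leg) or outside.

    Pushing trials require the declared sled side; sprint trials map the
    athlete's usual push side onto "corresponding" roles so paired
    comparisons align across activities.  Missing declarations leave
    steps unassigned (with a flag).
    """
    if side_of_sled not in ("left", "right"):
        for s in steps:
            s.leg_role = "unassigned"
            s.flags.append("no_sled_side_declared")
        return steps
    for s in steps:
        s.leg_role = "inside" if s.leading_foot == side_of_sled else "outside"
    return steps


def steps_to_frame(steps: list[Step], trial_id: str = "", athlete_id: str = "",
                   activity: str = "push") -> pd.DataFrame:
    rows = []
    for s in steps:
        rows.append(
            {
                "trial_id": trial_id, "athlete_id": athlete_id,
                "activity": activity, "step_index": s.index,
                "leading_foot": s.leading_foot, "leg_role": s.leg_role,
                "gct_s": s.gct, "ft_s": s.ft, "st_s": s.st, "sl_m": s.sl,
                "sf_hz": s.sf, "sv_ms": s.sv,
                "com_v_ms": s.com_step_velocity,
                "sled_v_ms": s.sled_step_velocity,
                "flags": ";".join(s.flags),
            }
        )
    return pd.DataFrame(rows)


def paired_step_differences(steps_by_athlete: dict[str, list[Step]],
                            variable: str):
    """Per-athlete (inside mean, outside mean) pairs for one variable.

    Athletes missing either role are excluded (logged in the returned
    report).  Raises ``ValueError`` when no athlete survives.
    """
    attr = {"sl": "sl", "sf": "sf", "sv": "sv", "gct": "gct", "ft": "ft",
            "st": "st"}[variable]
    inside, outside, kept, excluded = [], [], [], []
    for athlete, steps in steps_by_athlete.items():
        ins = [getattr(s, attr) for s in steps if s.leg_role == "inside"]
        out = [getattr(s, attr) for s in steps if s.leg_role == "outside"]
        if not ins or not out:
            excluded.append(athlete)
            continue
        inside.append(float(np.mean(ins)))
        outside.append(float(np.mean(out)))
        kept.append(athlete)
    if not kept:
        raise ValueError("no athlete has steps in both leg roles")
    return (np.asarray(inside), np.asarray(outside),
            {"athletes": kept, "excluded": excluded})
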