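"""Neonatal behavior metrics: swim alternation analysis and the
vestibulospinal rotate-overlay-displacement measurement.

Swimming is scored from per-hindlimb event trains: the times (and image
coordinates) of full flexion and full extension, typically digitized from
100 frames/s video.  Cycle period is the interval between successive full
flexions of one limb; left/right coordination is the circular phase of
right-hindlimb flexions within left-hindlimb cycles, computed by the same
phase engine used for ventral-root burst trains.  A cycle is a *missed
alternation* when its phase falls outside the half-cycle alternation window
[90°, 270°], and the miss ratio is the missed count divided by the mean
cycle period.

The vestibulospinal reflex is quantified by overlaying the start frame with
the maximal-extension frame rotated 90° counterclockwise and measuring the
distance between the hindpaw positions; when no extension occurs the frame
at 200 ms is used and the measurement is flagged.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .rhythm import PhaseSample, phases_from_onsets

__all__ = [
    "SwimBout",
    "swim_metrics",
    "vestibulo_displacement",
]

EVENT_TYPES = ("full_flexion", "full_extension")
ALTERNATION_WINDOW_DEG = (90.0, 270.0)


@dataclass(frozen=True)
class SwimBout:
    """Per-limb ordered flexion/extension events of one swimming episode.

    ``events`` is a table with columns ``limb`` (LH/RH), ``event``
    (full_flexion/full_extension), ``time_s``, ``x``, ``y``.  Within a limb,
    times must strictly increase and event types alternate.
    """

    events: pd.DataFrame
    frame_rate: float = 100.0
    bout_id: str = "bout"

    def __post_init__(self) -> None:
        df = self.events.copy().sort_values(["limb", "time_s"], kind="stable")
        df = df.reset_index(drop=True)
        object.__setattr__(self, "events", df)
        required = {"limb", "event", "time_s"}
        if not required.issubset(df.columns):
            raise ValueError(f"swim events need columns {sorted(required)}")
        if not set(df["event"]).issubset(EVENT_TYPES):
            raise ValueError(f"event types must be in {EVENT_TYPES}")
        for limb, grp in df.groupby("limb"):
            t = grp["time_s"].to_numpy(dtype=float)
            if np.any(np.diff(t) <= 0):
                raise ValueError(f"{limb}: event times must strictly increase")
            ev = grp["event"].to_numpy()
            if np.any(ev[1:] == ev[:-1]):
                raise ValueError(f"{limb}: flexion/extension must alternate")

    def flexion_times(self, limb: str) -> np.ndarray:
        sel = (self.events["limb"] == limb) & (self.events["event"] == "full_flexion")
        return self.events.loc[sel, "time_s"].to_numpy(dtype=float)


def swim_metrics(
    bout: SwimBout,
    cycle_event: str = "full_flexion",
    alternation_window_deg: tuple[float, float] = ALTERNATION_WINDOW_DEG,
) -> dict:
    """Per-limb cycle periods, LH->RH phases, missed alternations and miss ratio.

    ``cycle_event`` selects whether the cycle is delimited flexion-to-flexion
    (default) or extension-to-extension.  ``miss_ratio`` has units 1/s:
    missed alternation count divided by the mean cycle period in seconds.
    """
    if cycle_event not in EVENT_TYPES:
        raise ValueError(f"cycle_event must be one of {EVENT_TYPES}")
    times = {}
    for limb in ("LH", "RH"):
        sel = (bout.events["limb"] == limb) & (bout.events["event"] == cycle_event)
        t = bout.events.loc[sel, "time_s"].to_numpy(dtype=float)
        if t.size < 3:
            raise ValueError(f"{limb}: need at least 3 {cycle_event} events")
        times[limb] = t
    periods = {limb: np.diff(t) for limb, t in times.items()}
    mean_period = {limb: float(p.mean()) for limb, p in periods.items()}
    phases = phases_from_onsets(times["LH"], times["RH"], pair=("LH", "RH"))
    lo, hi = alternation_window_deg
    missed = int(np.count_nonzero((phases.phases < lo) | (phases.phases > hi)))
    overall_mean_period = float(np.mean([mean_period["LH"], mean_period["RH"]]))
    return {
        "cycle_periods_s": periods,
        "mean_cycle_period_s": mean_period,
        "phases": phases,
        "missed_alternations": missed,
        "miss_ratio_per_s": missed / overall_mean_period,
        "n_cycles": len(phases) + phases.n_skipped,
    }


def vestibulo_displacement(
    start_paw: tuple[float, float],
    end_paw: tuple[float, float],
    alignment: tuple[float, float] = (0.0, 0.0),
    center: tuple[float, float] = (0.0, 0.0),
    no_extension: bool = False,
) -> dict:
    """Paw displacement after the 90° counterclockwise rotate-and-overlay.

    The end-frame paw position is rotated 90° CCW about ``center``
    ((x, y) -> (-y, x) in centred coordinates), shifted by the manual
    ``alignment`` translation, and its Euclidean distance to the start-frame
    paw position is returned (same units as the coordinates, typically
    pixels or mm).  ``no_extension`` marks a measurement taken at the 200 ms
    fallback frame when no reflexive extension occurred.
    """
    sx, sy = start_paw
    ex, ey = end_paw
    if not all(np.isfinite([sx, sy, ex, ey])):
        raise ValueError("paw coordinates must be finite")
    cx, cy = center
    rx, ry = ex - cx, ey - cy
    qx, qy = -ry, rx  # 90 deg CCW
    px = qx + cx + alignment[0]
    py = qy + cy + alignment[1]
    dist = float(np.hypot(px - sx, py - sy))
    return {"displacement": dist, "no_extension": bool(no_extension)}
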