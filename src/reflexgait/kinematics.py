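"""Spatiotemporal gait parameters from paw contact/liftoff events.

Definitions (treadmill frame, SI units):

* cycle duration   -- time between successive contacts of the same limb
* stance duration  -- contact to liftoff of the same limb
* swing duration   -- cycle minus stance
* stride length    -- |x_contact - x_liftoff| plus the belt travel during
  swing (belt speed x swing duration)
* step length      -- horizontal distance between the leading and trailing
  limb at stance onset of the leading limb

Only cycles without a stimulation enter descriptive statistics of the
locomotor pattern; :func:`compute_cycles` flags stimulated cycles so callers
can drop them.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass
class GaitEventSeries:
    """Contact/liftoff times and horizontal paw positions for one limb.

    Events must alternate contact -> liftoff -> contact, with
    ``liftoff[i]`` strictly inside ``(contact[i], contact[i+1])``.
    Positions may be omitted (``None``) when only temporal measures are
    needed.
    """

    limb: str
    contact_times: np.ndarray
    liftoff_times: np.ndarray
    contact_x: np.ndarray | None = None
    liftoff_x: np.ndarray | None = None
    belt_speed: float = 0.0

    def __post_init__(self) -> None:
        self.contact_times = np.asarray(self.contact_times, dtype=float)
        self.liftoff_times = np.asarray(self.liftoff_times, dtype=float)
        if self.contact_x is not None:
            self.contact_x = np.asarray(self.contact_x, dtype=float)
        if self.liftoff_x is not None:
            self.liftoff_x = np.asarray(self.liftoff_x, dtype=float)
        self.validate()

    def validate(self) -> None:
        c, l = self.contact_times, self.liftoff_times
        if np.any(np.diff(c) <= 0):
            i = int(np.argmax(np.diff(c) <= 0))
            raise ValueError(f"{self.limb}: contact times not strictly increasing at index {i}")
        if len(l) not in (len(c), len(c) - 1):
            raise ValueError(
                f"{self.limb}: expected {len(c) - 1} or {len(c)} liftoffs, got {len(l)}"
            )
        for i in range(len(l)):
            if l[i] <= c[i]:
                raise ValueError(
                    f"{self.limb}: liftoff {i} at {l[i]:.4f} s is not after contact {i}"
                )
            if i + 1 < len(c) and l[i] >= c[i + 1]:
                raise ValueError(
                    f"{self.limb}: liftoff {i} at {l[i]:.4f} s is not before contact {i + 1}"
                )

    @property
    def n_cycles(self) -> int:
        return max(len(self.contact_times) - 1, 0)

    def span(self) -> tuple[float, float]:
        return float(self.contact_times[0]), float(self.contact_times[-1])


@dataclass
class StepCycle:
    """One locomotor cycle of one limb (all durations in s, lengths in m)."""

    limb: str
    index: int
    onset: float
    cycle_duration: float
    stance_duration: float
    swing_duration: float
    stride_length: float = np.nan
    has_stimulation: bool = False


def compute_cycles(
    series: GaitEventSeries, stim_times: np.ndarray | None = None
) -> list[StepCycle]:
    """Per-cycle durations and stride lengths for one limb.

    One cycle per consecutive contact pair; the last contact opens no cycle.
    A cycle is flagged as stimulated when a stimulus falls in
    ``[onset, next onset)`` (half-open convention).
    """
    c = series.contact_times
    cycles: list[StepCycle] = []
    stim = np.asarray(stim_times, dtype=float) if stim_times is not None else None
    for i in range(len(c) - 1):
        dur = c[i + 1] - c[i]
        stance = series.liftoff_times[i] - c[i]
        swing = dur - stance
        stimulated = bool(
            stim is not None and np.any((stim >= c[i]) & (stim < c[i + 1]))
        )
        cycles.append(
            StepCycle(
                limb=series.limb,
                index=i,
                onset=float(c[i]),
                cycle_duration=float(dur),
                stance_duration=float(stance),
                swing_duration=float(swing),
                stride_length=stride_length(series, i),
                has_stimulation=stimulated,
            )
        )
    return cycles


def stride_length(series: GaitEventSeries, cycle_index: int) -> float:
    """|x_contact - x_liftoff| + belt_speed * swing duration, in meters.

    Returns NaN (with a warning) when paw positions are missing.
    """
    i = cycle_index
    if series.contact_x is None or series.liftoff_x is None:
        warnings.warn(f"{series.limb}: no paw positions; stride length undefined")
        return float("nan")
    dur = series.contact_times[i + 1] - series.contact_times[i]
    swing = dur - (series.liftoff_times[i] - series.contact_times[i])
    dx = abs(series.contact_x[i] - series.liftoff_x[i])
    return float(dx + series.belt_speed * swing)


def limb_position(series: GaitEventSeries, t: float) -> float:
    """Horizontal paw position at time ``t`` interpolated from events.

    During stance the paw rides the belt backward from its contact position;
    during swing the paw moves linearly from its liftoff position to the
    next contact position.  Returns NaN outside the recorded span.
    """
    c, l = series.contact_times, series.liftoff_times
    if series.contact_x is None or series.liftoff_x is None:
        return float("nan")
    if t < c[0] or t > c[-1]:
        return float("nan")
    j = int(np.searchsorted(c, t, side="right")) - 1
    if j >= len(l) or t < l[j]:  # stance of cycle j (or exactly at its contact)
        return float(series.contact_x[j] - series.belt_speed * (t - c[j]))
    if j + 1 >= len(c):
        return float("nan")
    frac = (t - l[j]) / (c[j + 1] - l[j])
    return float(series.liftoff_x[j] + frac * (series.contact_x[j + 1] - series.liftoff_x[j]))


def step_length(
    leading: GaitEventSeries, trailing: GaitEventSeries, at_contact_index: int
) -> float:
    """Horizontal separation (m, >= 0) between the leading and trailing limb
    at stance onset of the leading limb; NaN when the instant falls outside
    the trailing limb's recorded span."""
    t = leading.contact_times[at_contact_index]
    x_lead = (
        leading.contact_x[at_contact_index] if leading.contact_x is not None else np.nan
    )
    x_trail = limb_position(trailing, float(t))
    return float(abs(x_lead - x_trail))


def cycles_table(
    all_series: dict[str, GaitEventSeries], stim_times: np.ndarray | None = None
) -> pd.DataFrame:
    """Tidy per-cycle table of the five spatiotemporal measures, all limbs."""
    rows = []
    for limb, series in all_series.items():
        for cyc in compute_cycles(series, stim_times):
            rows.append(
                {
                    "limb": limb,
                    "cycle": cyc.index,
                    "onset_s": cyc.onset,
                    "cycle_duration_s": cyc.cycle_duration,
                    "stance_duration_s": cyc.stance_duration,
                    "swing_duration_s": cyc.swing_duration,
                    "stride_length_m": cyc.stride_length,
                    "has_stimulation": cyc.has_stimulation,
                }
            )
    return pd.DataFrame(rows)
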