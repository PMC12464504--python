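"""Utility trajectories, QALY area-under-curve, and discounting.

A participant's health-related quality of life is observed at survey
waves as an EQ-5D-5L index (1 = full health, 0 = dead, negative values
allowed for states worse than death under some value sets). QALYs are
the area under the piecewise-linear utility-versus-time curve. Death is
an absorbing state: utility is 0 from the date of death onward, and the
segment between the last observation and death defaults to a linear
decline (a last-value-carried-forward step is available).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io import ValidationError

DIMENSIONS = ("MO", "SC", "UA", "PD", "AD")  # mobility, self-care, usual
# activities, pain/discomfort, anxiety/depression


@dataclass(frozen=True)
class ValueSetTable:
    """Additive value set mapping EQ-5D-5L profiles to a utility index.

    ``decrements[(dimension, level)]`` is the (nonnegative) utility loss
    for reporting ``level`` on ``dimension``; level 1 carries no loss.
    The index of profile d1d2d3d4d5 is ``anchor - sum(decrements)``, so
    the full-health profile 11111 maps to ``anchor`` (1.0).
    """

    decrements: Mapping[tuple[str, int], float]
    anchor: float = 1.0

    def __post_init__(self) -> None:
        for dim in DIMENSIONS:
            for level in range(1, 6):
                if (dim, level) not in self.decrements:
                    raise ValidationError(f"missing coefficient for {dim} level {level}")
        if any(v < 0 for v in self.decrements.values()):
            raise ValidationError("decrements must be >= 0")
        if any(self.decrements[(d, 1)] != 0 for d in DIMENSIONS):
            raise ValidationError("level-1 decrements must be 0 (full-health anchor)")

    @property
    def floor(self) -> float:
        """Index of the worst state 55555."""
        return self.anchor - sum(self.decrements[(d, 5)] for d in DIMENSIONS)


def read_value_set(path) -> ValueSetTable:
    """Read value-set coefficients from a CSV (dimension, level, decrement)."""
    df = pd.read_csv(path)
    dec = {
        (str(r.dimension), int(r.level)): float(r.decrement) for r in df.itertuples()
    }
    return ValueSetTable(dec)


def synthetic_value_set(floor: float = -0.391) -> ValueSetTable:
    """A synthetic additive value set for testing and simulation.

    Not a published national tariff: decrements rise smoothly with
    level and are scaled so the worst state 55555 maps to ``floor``.
    """
    weights = {"MO": 0.25, "SC": 0.21, "UA": 0.18, "PD": 0.20, "AD": 0.16}
    level_frac = {1: 0.0, 2: 0.18, 3: 0.40, 4: 0.72, 5: 1.0}
    scale = (1.0 - floor) / sum(weights.values())
    dec = {
        (d, lv): weights[d] * scale * level_frac[lv]
        for d in DIMENSIONS
        for lv in range(1, 6)
    }
    return ValueSetTable(dec)


def profile_to_utility(profile: str | int, vs: ValueSetTable) -> float:
    """Convert a 5-digit EQ-5D-5L profile to a utility index."""
    s = str(profile)
    if len(s) != 5 or not s.isdigit():
        raise ValidationError(f"profile must be 5 digits, got {profile!r}")
    levels = [int(c) for c in s]
    if any(not 1 <= lv <= 5 for lv in levels):
        raise ValidationError(f"profile digits must be in 1..5, got {profile!r}")
    return vs.anchor - sum(vs.decrements[(d, lv)] for d, lv in zip(DIMENSIONS, levels))


@dataclass(frozen=True)
class UtilityTrajectory:
    """Piecewise-linear utility over time for one participant.

    ``points`` are the trajectory breakpoints (time in years since
    baseline, utility), already including any death handling; utility
    between breakpoints is linear. The trajectory is defined on
    [0, points[-1].time] — survivors are never extrapolated past their
    last observation.
    """

    participant_id: object
    points: tuple[tuple[float, float], ...]
    death_time: float | None
    horizon: float

    def __post_init__(self) -> None:
        t = np.array([p[0] for p in self.points])
        if np.any(np.diff(t) < 0):
            raise ValidationError("breakpoint times must be nondecreasing")
        if any(p[1] > 1.0 + 1e-12 for p in self.points):
            raise ValidationError("utilities must be <= 1")

    @property
    def end_time(self) -> float:
        return self.points[-1][0]

    def utility_at(self, t: float) -> float:
        times = np.array([p[0] for p in self.points])
        utils = np.array([p[1] for p in self.points])
        if t < times[0] or t > times[-1]:
            raise ValueError(f"t={t} outside trajectory support [0, {times[-1]}]")
        return float(np.interp(t, times, utils))


def build_trajectory(
    measurements: Sequence[tuple[float, float]],
    death_time: float | None = None,
    horizon: float = 1.0,
    participant_id: object = None,
    death_transition: str = "linear",
) -> UtilityTrajectory:
    """Assemble a utility trajectory from wave measurements.

    Observed waves are interpolated linearly (which also fills missing
    interior waves). If the participant died, utility is 0 from
    ``death_time`` to ``horizon``; the segment from the last observation
    to death is a linear decline by default, or a step at death when
    ``death_transition="locf"``.
    """
    if not measurements:
        raise ValidationError("at least one measurement required")
    pts = sorted((float(t), float(u)) for t, u in measurements)
    if abs(pts[0][0]) > 1e-9:
        raise ValidationError("a baseline (t=0) measurement is required")
    if death_time is not None:
        if death_time <= 0:
            raise ValidationError("death before baseline")
        pts = [p for p in pts if p[0] <= death_time + 1e-12]
        last_t, last_u = pts[-1]
        if death_transition == "linear":
            if death_time > last_t:
                pts.append((float(death_time), 0.0))
            else:
                pts[-1] = (float(death_time), 0.0)
        elif death_transition == "locf":
            if death_time > last_t:
                pts.append((float(death_time), last_u))
            pts.append((float(death_time), 0.0))
        else:
            raise ValueError(f"unknown death_transition {death_transition!r}")
        if horizon > death_time:
            pts.append((float(horizon), 0.0))
    return UtilityTrajectory(
        participant_id=participant_id,
        points=tuple(pts),
        death_time=death_time,
        horizon=float(horizon),
    )


def qaly_auc(traj: UtilityTrajectory, window: tuple[float, float]) -> float:
    """QALYs over ``window`` by trapezoidal area under the trajectory."""
    t0, t1 = float(window[0]), float(window[1])
    if t1 <= t0:
        raise ValidationError(f"window must have t1 > t0, got {window}")
    if t0 < 0 or t1 > traj.horizon + 1e-12:
        raise ValidationError(f"window {window} outside [0, horizon={traj.horizon}]")
    if t1 > traj.end_time + 1e-12:
        raise ValidationError(
            f"window end {t1} past last defined time {traj.end_time}; "
            "survivor utilities are not extrapolated"
        )
    # integrate segment-wise over stored breakpoints so zero-width
    # steps (e.g. a carried-forward utility dropping to 0 at death)
    # contribute nothing instead of corrupting interpolation
    area = 0.0
    pts = traj.points
    for (ta, ua), (tb, ub) in zip(pts[:-1], pts[1:]):
        lo, hi = max(ta, t0), min(tb, t1)
        if hi <= lo or tb == ta:
            continue
        ua_ = ua + (ub - ua) * (lo - ta) / (tb - ta)
        ub_ = ua + (ub - ua) * (hi - ta) / (tb - ta)
        area += 0.5 * (ua_ + ub_) * (hi - lo)
    return float(area)


def annual_qalys(traj: UtilityTrajectory, n_years: int | None = None) -> list[float]:
    """Per-year QALYs (calendar years from baseline, last year pro-rated)."""
    end = min(traj.end_time, traj.horizon)
    if n_years is None:
        n_years = int(np.ceil(end - 1e-12))
    out = []
    for k in range(n_years):
        hi = min(k + 1.0, end)
        if hi <= k:
            out.append(0.0)
        else:
            out.append(qaly_auc(traj, (float(k), hi)))
    return out


def discount_stream(values_by_year: Mapping[int, float], rate: float) -> float:
    """Present value of a yearly stream: sum of v_t / (1+rate)^t.

    Year indices are whole years since the discounting anchor (year 0
    is undiscounted, year 1 divided by (1+rate), ...).
    """
    if rate < 0:
        raise ValidationError("discount rate must be >= 0")
    return float(sum(v / (1.0 + rate) ** int(t) for t, v in values_by_year.items()))
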