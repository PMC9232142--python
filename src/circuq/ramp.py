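"""Pump-speed ramp study: clinical criteria and feasible speed windows.

Sweeps rotor speed (and optionally heart rate and ejection fraction), runs
the 0D model per cell, and evaluates the two clinical criteria: complete
aortic valve opening (QAo_avg > 5e-6 m^3/s, i.e. 0.3 L/min) and a cardiac
output compatible with life (Qtot_avg > 7e-5 m^3/s, i.e. 4.2 L/min, the
2.2 L/min/m^2 cardiac index at a 1.9 m^2 body surface area).

H-Q curves are only measured at 0, 8k and 11k rpm; intermediate (and
ramp-top 12k) speeds use linear interpolation/extrapolation of (a, b) in
speed, flagged in the report.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model import (
    BeatingMode,
    PUMP_CURVES,
    PumpCurve,
    QoISet,
    default_config,
    extract_qois,
    simulate,
)

__all__ = [
    "RampCriteria",
    "m3s_to_lmin",
    "lmin_to_m3s",
    "desired_output",
    "ramp_speeds",
    "pump_curve_for_speed",
    "evaluate_criteria",
    "run_ramp",
    "speed_window",
]


@dataclass(frozen=True)
class RampCriteria:
    """Clinical thresholds, strict inequalities."""

    aov_open_threshold: float = 5.0e-6  # m^3/s, complete AoV opening
    co_threshold: float = 7.0e-5  # m^3/s, cardiac output compatible with life
    cardiac_index: float = 2.2  # L/min/m^2
    BSA: float = 1.9  # m^2

    def __post_init__(self) -> None:
        if self.aov_open_threshold <= 0 or self.co_threshold <= 0:
            raise ValueError("thresholds must be positive")


def m3s_to_lmin(q: float) -> float:
    """m^3/s -> L/min."""
    return q * 60000.0


def lmin_to_m3s(q: float) -> float:
    """L/min -> m^3/s."""
    return q / 60000.0


def desired_output(BSA: float, index: float = 2.2) -> float:
    """Desired cardiac output [L/min] for a body surface area [m^2]."""
    if BSA <= 0:
        raise ValueError("BSA must be positive")
    return index * BSA


def ramp_speeds(start: float = 8000, step: float = 400, stop: float = 12000):
    """Ramp-protocol speed list: inclusive arithmetic sequence [rpm]."""
    if step <= 0:
        raise ValueError("step must be positive")
    if stop < start:
        raise ValueError("stop must be >= start")
    n = int(round((stop - start) / step))
    speeds = [start + k * step for k in range(n + 1)]
    if speeds[-1] != stop:
        speeds.append(stop)
    return speeds


def pump_curve_for_speed(speed: float) -> tuple[PumpCurve, bool]:
    """H-Q curve at ``speed``; exact at the measured anchors, linearly
    interpolated/extrapolated in (a, b) otherwise.

    Returns (curve, interpolated_flag).
    """
    if speed < 0:
        raise ValueError("speed must be non-negative")
    if speed == 0:
        return PUMP_CURVES[0], False
    key = int(round(speed))
    if key in PUMP_CURVES and PUMP_CURVES[key].speed == speed:
        return PUMP_CURVES[key], False
    lo, hi = PUMP_CURVES[8000], PUMP_CURVES[11000]
    w = (speed - lo.speed) / (hi.speed - lo.speed)
    a = lo.a + w * (hi.a - lo.a)
    b = lo.b + w * (hi.b - lo.b)
    return PumpCurve(speed=speed, a=a, b=b, c=0.0), True


def evaluate_criteria(qois: QoISet, crit: RampCriteria = RampCriteria()):
    """(aov_open, co_ok) flags; both comparisons are strict."""
    aov_open = qois.QAo_avg > crit.aov_open_threshold
    co_ok = qois.Qtot_avg > crit.co_threshold
    return aov_open, co_ok


def run_ramp(
    HRs=(68.42,),
    EFs=(0.22,),
    speeds=None,
    crit: RampCriteria = RampCriteria(),
    ESV: float = 180.0e-6,
    **config_kwargs,
):
    """Evaluate the ramp grid; returns a flat pandas table.

    One row per (HR, EF, speed) cell with the QoIs (SI and L/min), the
    criteria flags and whether the H-Q curve was interpolated.
    """
    import pandas as pd

    if speeds is None:
        speeds = ramp_speeds()
    rows = []
    for hr in HRs:
        for ef in EFs:
            mode = BeatingMode(HR=hr, ESV=ESV, EF=ef)
            for speed in speeds:
                pump, interp = pump_curve_for_speed(speed)
                cfg = default_config(mode=mode, pump=pump, **config_kwargs)
                q = extract_qois(simulate(cfg), cfg)
                aov_open, co_ok = evaluate_criteria(q, crit)
                row = {"HR": hr, "EF": ef, "speed": speed}
                row.update(q.as_dict())
                row.update({
                    "QAo_avg_lmin": m3s_to_lmin(q.QAo_avg),
                    "Qtot_avg_lmin": m3s_to_lmin(q.Qtot_avg),
                    "aov_open": aov_open,
                    "co_ok": co_ok,
                    "interpolated": interp,
                })
                rows.append(row)
    return pd.DataFrame(rows)


def speed_window(grid, crit: RampCriteria = RampCriteria()):
    """Per-(HR, EF) maximal contiguous feasible speed interval.

    ``grid`` is the table from :func:`run_ramp`.  A cell is feasible when both
    flags hold; an empty window is reported as None, not an error.
    """
    out: dict[tuple[float, float], tuple[float, float] | None] = {}
    for (hr, ef), sub in grid.groupby(["HR", "EF"]):
        sub = sub.sort_values("speed")
        if len(sub) < 2:
            raise ValueError("speed_window needs at least two speeds per cell")
        feasible = (sub["aov_open"] & sub["co_ok"]).to_numpy()
        speeds = sub["speed"].to_numpy()
        best: tuple[float, float] | None = None
        best_len = 0
        i = 0
        while i < len(feasible):
            if feasible[i]:
                j = i
                while j + 1 < len(feasible) and feasible[j + 1]:
                    j += 1
                if j - i + 1 > best_len:
                    best_len = j - i + 1
                    best = (float(speeds[i]), float(speeds[j]))
                i = j + 1
            else:
                i += 1
        out[(float(hr), float(ef))] = best
    return out
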