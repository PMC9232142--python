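"""Forward uncertainty propagation and Minkowski-L1 validation metrics.

Six validation points (two beating conditions x three pump speeds) are
propagated through the 0D model by Latin hypercube sampling of the reduced
input set (EF, HR and the pump H-Q coefficients a, b).  Simulation output
ensembles are summarised as ECDFs and compared to the measured quantity of
interest through the Minkowski L1 (area) metric in two forms: MN^u against a
uniform distribution over the measured +-10% band, and the p-box bounds MN-
and MN+ against degenerate CDFs at the band's limits.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .model import (
    BeatingMode,
    PumpCurve,
    QoISet,
    QOI_NAMES,
    default_config,
    extract_qois,
    simulate,
)
from .sensitivity import InputSpec, lhs_sample

__all__ = [
    "ValidationPoint",
    "ECDF",
    "PBox",
    "MNMetrics",
    "ValidationReport",
    "VALIDATION_POINTS",
    "ecdf",
    "uniform_band",
    "minkowski_u",
    "minkowski_pbox",
    "simulation_model",
    "run_uq",
    "load_measured_table",
]


@dataclass(frozen=True)
class ValidationPoint:
    """One bench operating condition with its UQ input ranges.

    ``a_range``/``b_range`` are None for the pump-off (clamped) points, where
    the H-Q coefficients are deterministically zero.
    """

    label: str
    speed: float  # rpm
    EF_range: tuple[float, float]
    HR_range: tuple[float, float]
    a_range: tuple[float, float] | None = None
    b_range: tuple[float, float] | None = None
    n_samples: int = 50
    ESV: float = 180.0e-6

    def input_specs(self) -> list[InputSpec]:
        specs = [
            InputSpec("EF", "aleatory", *self.EF_range, units="-"),
            InputSpec("HR", "aleatory", *self.HR_range, units="bpm"),
        ]
        if self.a_range is not None:
            specs.append(InputSpec("a", "aleatory", *self.a_range, units="Pa"))
            specs.append(InputSpec("b", "aleatory", *self.b_range, units="Pa.s/m^3"))
        return specs


def _vp(label, speed, ef, hr, a=None, b=None):
    return ValidationPoint(label=label, speed=speed, EF_range=ef, HR_range=hr,
                           a_range=a, b_range=b)


#: The six validation points: EF/HR ranges are the bench settings +-10%; the
#: 8k/11k H-Q coefficient ranges come from the fit-uncertainty analysis.
VALIDATION_POINTS: tuple[ValidationPoint, ...] = (
    _vp("22%@68.42bpm/0k", 0, (0.198, 0.242), (65.55, 72.45)),
    _vp("22%@68.42bpm/8k", 8000, (0.198, 0.242), (65.55, 72.45),
        (10.91e3, 12.66e3), (-7.90e7, -7.53e7)),
    _vp("22%@68.42bpm/11k", 11000, (0.198, 0.242), (65.55, 72.45),
        (19.64e3, 23.77e3), (-9.80e7, -8.24e7)),
    _vp("17%@61.18bpm/0k", 0, (0.153, 0.187), (53.0, 63.0)),
    _vp("17%@61.18bpm/8k", 8000, (0.153, 0.187), (53.0, 63.0),
        (10.91e3, 12.66e3), (-7.90e7, -7.53e7)),
    _vp("17%@61.18bpm/11k", 11000, (0.153, 0.187), (53.0, 63.0),
        (19.64e3, 23.77e3), (-9.80e7, -8.24e7)),
)


# ---------------------------------------------------------------------------
# distributions and metrics
# ---------------------------------------------------------------------------


class ECDF:
    """Right-continuous empirical CDF of a sample."""

    def __init__(self, values):
        v = np.sort(np.asarray(values, dtype=float).ravel())
        if v.size == 0:
            raise ValueError("ECDF needs at least one value")
        self.values = v
        self.n = v.size

    def __call__(self, q):
        return np.searchsorted(self.values, np.asarray(q, dtype=float),
                               side="right") / self.n

    @property
    def support(self) -> tuple[float, float]:
        return float(self.values[0]), float(self.values[-1])


def ecdf(values) -> ECDF:
    """Empirical cumulative distribution function of ``values``."""
    return ECDF(values)


@dataclass(frozen=True)
class PBox:
    """Interval bound on the measured quantity; optionally read as uniform."""

    lower: float
    upper: float
    assume_uniform: bool = False

    def __post_init__(self) -> None:
        if self.lower > self.upper:
            raise ValueError("require lower <= upper")


def uniform_band(measured: float, frac: float = 0.10) -> PBox:
    """The measured value +- ``frac`` relative error, flagged uniform."""
    if frac < 0:
        raise ValueError("frac must be non-negative")
    a, b = measured * (1.0 - frac), measured * (1.0 + frac)
    return PBox(lower=min(a, b), upper=max(a, b), assume_uniform=True)


def _l1_vs_step(sim: ECDF, where: float) -> float:
    """Exact L1 distance between ``sim`` and the degenerate CDF at ``where``.

    The area between an ECDF and a unit step collapses to E|X - where|.
    """
    return float(np.mean(np.abs(sim.values - where)))


def _uniform_cdf(q, lo: float, hi: float):
    if hi == lo:
        return (np.asarray(q) >= lo).astype(float)
    return np.clip((np.asarray(q, dtype=float) - lo) / (hi - lo), 0.0, 1.0)


def minkowski_u(sim: ECDF, band: PBox) -> float:
    """MN^u: area between the simulation ECDF and the band's uniform CDF.

    Computed by exact piecewise integration: between breakpoints the ECDF is
    constant and the uniform CDF linear, so each piece integrates in closed
    form (splitting at the interior crossing when the sign changes).
    """
    if not band.assume_uniform:
        raise ValueError("minkowski_u requires a band flagged assume_uniform")
    lo, hi = band.lower, band.upper
    if hi == lo:
        return _l1_vs_step(sim, lo)
    pts = np.unique(np.concatenate([sim.values, [lo, hi]]))
    total = 0.0
    # below the first breakpoint and above the last both CDFs agree (0 or 1)
    for q0, q1 in zip(pts[:-1], pts[1:]):
        f_sim = float(sim(q0))  # constant on [q0, q1)
        u0 = float(_uniform_cdf(q0, lo, hi))
        u1 = float(_uniform_cdf(q1, lo, hi))
        d0, d1 = f_sim - u0, f_sim - u1
        w = q1 - q0
        if d0 * d1 >= 0:
            total += 0.5 * (abs(d0) + abs(d1)) * w
        else:
            qc = w * d0 / (d0 - d1)
            total += 0.5 * (abs(d0) * qc + abs(d1) * (w - qc))
    return total


def minkowski_pbox(sim: ECDF, band: PBox) -> tuple[float, float]:
    """(MN-, MN+): L1 distances to unit steps at the band's lower and upper
    limits (the p-box bounds when no distribution is assumed)."""
    return _l1_vs_step(sim, band.lower), _l1_vs_step(sim, band.upper)


@dataclass(frozen=True)
class MNMetrics:
    mn_u: float
    mn_minus: float
    mn_plus: float


@dataclass
class ValidationReport:
    """Per-point validation metrics for every QoI [m^3/s]."""

    label: str
    metrics: dict[str, MNMetrics]
    n: int
    n_failed: int = 0
    flagged: bool = False

    def as_rows(self):
        for qoi, m in self.metrics.items():
            yield {
                "point": self.label, "qoi": qoi, "MN_u": m.mn_u,
                "MN_minus": m.mn_minus, "MN_plus": m.mn_plus,
                "n": self.n, "n_failed": self.n_failed,
            }


# ---------------------------------------------------------------------------
# forward propagation
# ---------------------------------------------------------------------------


def simulation_model(inputs: dict, point: ValidationPoint, **config_kwargs) -> QoISet:
    """Run the 0D model at one sampled input set of a validation point."""
    mode = BeatingMode(HR=inputs["HR"], ESV=point.ESV, EF=inputs["EF"])
    if point.a_range is None:
        pump = PumpCurve(speed=0, clamped=True)
    else:
        pump = PumpCurve(speed=point.speed, a=inputs["a"], b=inputs["b"], c=0.0)
    cfg = default_config(mode=mode, pump=pump, **config_kwargs)
    return extract_qois(simulate(cfg), cfg)


def run_uq(
    points=VALIDATION_POINTS,
    model=simulation_model,
    n: int | None = None,
    seed: int | None = None,
    comparator=None,
    band_frac: float = 0.10,
    min_success: float = 0.8,
):
    """Propagate each validation point and compute validation metrics.

    ``model(inputs, point)`` maps one sampled input dict to a :class:`QoISet`;
    failures are captured and counted.  ``comparator(point)`` returns the
    measured QoI values (dict name -> value) the +-``band_frac`` band is built
    from; without one only the ensembles are returned.  Returns
    ``(ensembles, reports)`` where ensembles maps point label -> QoI name ->
    sample vector.
    """
    ensembles: dict[str, dict[str, np.ndarray]] = {}
    reports: list[ValidationReport] = []
    for k, point in enumerate(points):
        n_pt = n if n is not None else point.n_samples
        pt_seed = None if seed is None else (seed * 7919 + k) % (2**31)
        samples = lhs_sample(point.input_specs(), n_pt, seed=pt_seed)
        qois: dict[str, list[float]] = {name: [] for name in QOI_NAMES}
        n_failed = 0
        for row in samples.rows():
            try:
                q = model(row, point)
            except Exception:
                n_failed += 1
                continue
            for name, val in q.as_dict().items():
                qois[name].append(val)
        ens = {name: np.asarray(v) for name, v in qois.items()}
        ensembles[point.label] = ens
        if comparator is None:
            continue
        measured = comparator(point)
        n_ok = n_pt - n_failed
        flagged = n_ok < min_success * n_pt
        metrics: dict[str, MNMetrics] = {}
        if n_ok > 0:
            for name, vals in ens.items():
                if name not in measured:
                    continue
                band = uniform_band(measured[name], band_frac)
                F = ecdf(vals)
                mn_minus, mn_plus = minkowski_pbox(F, band)
                metrics[name] = MNMetrics(
                    mn_u=minkowski_u(F, band),
                    mn_minus=mn_minus,
                    mn_plus=mn_plus,
                )
        reports.append(ValidationReport(
            label=point.label, metrics=metrics, n=n_ok,
            n_failed=n_failed, flagged=flagged,
        ))
    return ensembles, reports


def load_measured_table(path):
    """Read measured QoIs from a delimited text table.

    Expected columns: point, then one column per QoI name.  Returns a
    comparator callable for :func:`run_uq`.
    """
    import pandas as pd

    df = pd.read_csv(path, sep=None, engine="python").set_index("point")

    def comparator(point: ValidationPoint) -> dict[str, float]:
        return df.loc[point.label].to_dict()

    return comparator
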