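"""Code and calculation verification utilities.

Analytic oracles for steady (Poiseuille) and pulsatile (Womersley) pipe flow,
relative RMS error, observed order of convergence and the grid convergence
index (GCI), plus a dt-refinement study of the package's own Windkessel
integrator.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.special import jv

from .model import FluidProperties, Windkessel3E, windkessel_advance

__all__ = [
    "AnalyticFlowSpec",
    "GridStudy",
    "ConvergenceReport",
    "poiseuille_velocity",
    "womersley_velocity",
    "rmse_percent",
    "observed_order",
    "gci",
    "convergence_report",
    "windkessel_dt_study",
]


@dataclass(frozen=True)
class AnalyticFlowSpec:
    """Pipe-flow problem: radius, axial pressure-gradient amplitude G
    (amplitude of -dp/dx, [Pa/m]) and angular frequency (0 for steady)."""

    radius: float
    gradient: float
    omega: float = 0.0
    fluid: FluidProperties = FluidProperties()

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ValueError("radius must be positive")
        if self.omega < 0:
            raise ValueError("omega must be non-negative")

    @property
    def alpha(self) -> float:
        """Womersley number R sqrt(omega rho / mu)."""
        return self.radius * math.sqrt(self.omega * self.fluid.rho / self.fluid.mu)


def poiseuille_velocity(rpos, spec: AnalyticFlowSpec):
    """Steady axial velocity u(r) = G (R^2 - r^2) / (4 mu)."""
    r = np.asarray(rpos, dtype=float)
    if np.any(np.abs(r) > spec.radius * (1 + 1e-12)):
        raise ValueError("radial position outside the pipe")
    u = spec.gradient * (spec.radius**2 - r**2) / (4.0 * spec.fluid.mu)
    return float(u) if np.isscalar(rpos) else u


def womersley_velocity(rpos, t, spec: AnalyticFlowSpec):
    """Pulsatile axial velocity for -dp/dx = G cos(omega t).

    u(r, t) = Re{ (G / (i rho omega)) [1 - J0(i^{3/2} alpha r/R) /
    J0(i^{3/2} alpha)] e^{i omega t} }, with i^{3/2} = e^{i 3 pi / 4}.  In the
    alpha -> 0 limit this reduces to the quasi-steady Poiseuille profile.
    """
    if spec.omega <= 0:
        raise ValueError("womersley_velocity requires omega > 0")
    r = np.asarray(rpos, dtype=float)
    if np.any(np.abs(r) > spec.radius * (1 + 1e-12)):
        raise ValueError("radial position outside the pipe")
    i32 = np.exp(1j * 3.0 * np.pi / 4.0)
    alpha = spec.alpha
    xi = r / spec.radius
    profile = 1.0 - jv(0, i32 * alpha * xi) / jv(0, i32 * alpha)
    amp = spec.gradient / (1j * spec.fluid.rho * spec.omega)
    u = np.real(amp * profile * np.exp(1j * spec.omega * np.asarray(t)))
    return float(u) if np.isscalar(rpos) and np.isscalar(t) else u


def rmse_percent(numeric, reference) -> float:
    """100 * RMS(numeric - reference) / RMS(reference)."""
    a = np.asarray(numeric, dtype=float)
    b = np.asarray(reference, dtype=float)
    if a.shape != b.shape:
        raise ValueError("numeric and reference must have equal shape")
    ref_norm = math.sqrt(float(np.mean(b**2)))
    if ref_norm == 0.0:
        raise ValueError("reference signal has zero norm")
    return 100.0 * math.sqrt(float(np.mean((a - b) ** 2))) / ref_norm


@dataclass(frozen=True)
class GridStudy:
    """Systematic-refinement study, coarsest first / finest last.

    ``values`` are discretisation errors against an exact solution when
    ``values_are_errors`` (the default), or solution values themselves for
    three-level Richardson analysis without an exact solution.
    """

    values: tuple
    r: float
    p_th: float = 2.0
    Fs: float | None = None
    values_are_errors: bool = True

    def __post_init__(self) -> None:
        if len(self.values) < 2:
            raise ValueError("need at least two refinement levels")
        if self.r <= 1.0:
            raise ValueError("refinement ratio must exceed 1")


@dataclass(frozen=True)
class ConvergenceReport:
    p_obs: float
    gci_percent: float
    extrapolated: float | None
    monotone: bool


def observed_order(study: GridStudy) -> float:
    """Observed order of convergence.

    Against an exact solution: p = ln(e_coarse / e_fine) / ln(r) on the two
    finest levels.  Without one, the three-level Richardson formula
    p = ln((f1 - f2) / (f2 - f3)) / ln(r) with f3 the finest solution.
    """
    v = study.values
    if study.values_are_errors:
        e_coarse, e_fine = v[-2], v[-1]
        if e_fine <= 0 or e_coarse <= 0:
            raise ValueError("errors must be positive")
        return math.log(e_coarse / e_fine) / math.log(study.r)
    if len(v) < 3:
        raise ValueError("Richardson order estimate needs three solution levels")
    d21, d32 = v[-2] - v[-3], v[-1] - v[-2]
    if d32 == 0 or d21 / d32 <= 0:
        raise ValueError("solution differences do not permit an order estimate")
    return math.log(abs(d21) / abs(d32)) / math.log(study.r)


def _is_monotone(study: GridStudy) -> bool:
    if not study.values_are_errors:
        return True
    return all(a > b for a, b in zip(study.values, study.values[1:]))


def gci(study: GridStudy, p: float, fine: float | None = None,
        coarse: float | None = None) -> float:
    """Grid convergence index (percent) on the finest level.

    GCI = Fs |eps| / (r^p - 1) * 100 with eps = (f_coarse - f_fine)/f_fine.
    Fs defaults to 1.25 for three or more levels and 3.0 for two (the usual
    95%-confidence safety factors).  When the study holds errors rather than
    solution values, pass the fine/coarse solutions explicitly.
    """
    if p <= 0:
        raise ValueError("order must be positive")
    if fine is None or coarse is None:
        if study.values_are_errors:
            raise ValueError("GCI needs solution values, not errors")
        fine, coarse = study.values[-1], study.values[-2]
    if fine == 0:
        raise ValueError("fine solution is zero; relative eps undefined")
    denom = study.r**p - 1.0
    if denom == 0:
        raise ValueError("r^p = 1: GCI undefined")
    fs = study.Fs if study.Fs is not None else (1.25 if len(study.values) >= 3 else 3.0)
    eps = (coarse - fine) / fine
    return 100.0 * fs * abs(eps) / denom


def convergence_report(study: GridStudy) -> ConvergenceReport:
    """Observed order, GCI and Richardson-extrapolated value for a study."""
    p = observed_order(study)
    if study.values_are_errors:
        g = float("nan")
        extrap = None
    else:
        g = gci(study, p)
        f1, f2 = study.values[-1], study.values[-2]
        extrap = f1 + (f1 - f2) / (study.r**p - 1.0)
    return ConvergenceReport(p_obs=p, gci_percent=g, extrapolated=extrap,
                             monotone=_is_monotone(study))


def windkessel_dt_study(
    dts=(0.016, 0.008, 0.004, 0.002),
    wk: Windkessel3E | None = None,
    horizon: float = 1.0,
) -> GridStudy:
    """Temporal-refinement study of the trapezoidal Windkessel integrator.

    Integrates the free decay (Q_in = 0) whose exact solution is
    Pc0 exp(-t / (Rp Cp)) and reports the end-time absolute error per dt.
    The trapezoidal rule is second order, so the observed order should
    approach 2.
    """
    dts = tuple(sorted(dts, reverse=True))
    ratios = {round(dts[i] / dts[i + 1], 12) for i in range(len(dts) - 1)}
    if len(ratios) != 1:
        raise ValueError("dt sequence must use a constant refinement ratio")
    r = ratios.pop()
    if wk is None:
        wk = Windkessel3E()
    tau = wk.Rp * wk.Cp
    errors = []
    for dt in dts:
        n = int(round(horizon / dt))
        state = wk
        for _ in range(n):
            _, state = windkessel_advance(0.0, state, dt)
        exact = wk.Pc * math.exp(-n * dt / tau)
        errors.append(abs(state.Pc - exact))
    return GridStudy(values=tuple(errors), r=r, p_th=2.0)
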