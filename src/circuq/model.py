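"""0D lumped-parameter model of a left ventricle with an apical LVAD.

The model mirrors the working principle of a piston-driven mock circulation
loop: a prescribed ventricular volume waveform forces flow through two
pressure-driven valves (mitral, aortic), a rotary-pump H-Q boundary condition
and a 3-element Windkessel afterload.  The left atrium is a constant-pressure
reservoir.  Because the volume is prescribed, the left-ventricular pressure is
the unknown closing the per-step mass balance

    Q_MV - Q_AoV - Q_VAD = dV/dt.

All quantities are strict SI (m^3, Pa, s, m^3/s); unit conversions live in
:mod:`circuq.ramp`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import yaml

__all__ = [
    "ConfigurationError",
    "SolverError",
    "FluidProperties",
    "BeatingMode",
    "VolumeWaveform",
    "ValveLaw",
    "PumpCurve",
    "Windkessel3E",
    "CirculationConfig",
    "SimulationResult",
    "QoISet",
    "PUMP_CURVES",
    "MODE_22",
    "MODE_17",
    "prescribed_volume",
    "valve_porosity",
    "median_filter",
    "valve_flow",
    "pump_flow",
    "windkessel_advance",
    "solve_lv_pressure",
    "simulate",
    "extract_qois",
    "default_config",
    "load_config",
    "save_config",
    "result_to_frame",
]


class ConfigurationError(ValueError):
    """Invalid model configuration."""


class SolverError(RuntimeError):
    """The per-step pressure solve could not bracket or converge on a root."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class FluidProperties:
    """Blood-analogue fluid: 40% glycerol/saline at room temperature."""

    rho: float = 1100.0  # kg/m^3
    mu: float = 3.72e-3  # Pa.s

    def __post_init__(self) -> None:
        if self.rho <= 0 or self.mu <= 0:
            raise ConfigurationError("rho and mu must be positive")


@dataclass(frozen=True)
class BeatingMode:
    """Ventricular beating condition.

    EF, EDV and ESV are linked by EF = (EDV - ESV) / EDV; exactly one of
    ``EF``/``EDV`` may be omitted and is filled in by the constructor.
    """

    HR: float  # beats per minute
    ESV: float  # m^3
    EDV: float | None = None  # m^3
    EF: float | None = None  # dimensionless

    def __post_init__(self) -> None:
        if self.HR <= 0:
            raise ConfigurationError("HR must be positive")
        if self.ESV <= 0:
            raise ConfigurationError("ESV must be positive")
        if self.EDV is None and self.EF is None:
            raise ConfigurationError("one of EDV, EF is required")
        if self.EDV is None:
            if not 0.0 < self.EF < 1.0:
                raise ConfigurationError("EF must lie in (0, 1)")
            object.__setattr__(self, "EDV", self.ESV / (1.0 - self.EF))
        elif self.EF is None:
            object.__setattr__(self, "EF", (self.EDV - self.ESV) / self.EDV)
        if not self.ESV < self.EDV:
            raise ConfigurationError("require 0 < ESV < EDV")
        if abs(self.EF - (self.EDV - self.ESV) / self.EDV) > 1e-9:
            raise ConfigurationError("EF inconsistent with EDV/ESV")

    @property
    def period(self) -> float:
        """Beat period in seconds."""
        return 60.0 / self.HR

    @property
    def stroke_volume(self) -> float:
        return self.EDV - self.ESV


#: Bench beating condition "22%@68.42bpm" (EF derived from the volumes).
MODE_22 = BeatingMode(HR=68.42, ESV=180.0e-6, EDV=230.0e-6)
#: Bench beating condition "17%@61.18bpm".
MODE_17 = BeatingMode(HR=61.18, ESV=180.0e-6, EDV=216.86e-6)


@dataclass(frozen=True)
class VolumeWaveform:
    """Piston-prescribed ventricular volume over one beat.

    Four raised-cosine phases, in beat order: a diastasis *plateau* just below
    EDV, the *atrial kick* completing the fill to EDV, systolic *ejection*
    down to ESV, and passive diastolic *filling* back up to the plateau level.
    The kick amplitude is ``kick_fraction`` of the stroke volume.  All phase
    durations are fractions of the period and must sum to one.
    """

    mode: BeatingMode
    plateau: float = 0.15
    kick: float = 0.15
    systole: float = 0.30
    diastole: float = 0.40
    kick_fraction: float = 0.10

    def __post_init__(self) -> None:
        fracs = (self.plateau, self.kick, self.systole, self.diastole)
        if any(f < 0 for f in fracs):
            raise ConfigurationError("phase fractions must be non-negative")
        if abs(sum(fracs) - 1.0) > 1e-9:
            raise ConfigurationError("phase fractions must sum to 1")
        if not 0.0 <= self.kick_fraction < 1.0:
            raise ConfigurationError("kick_fraction must lie in [0, 1)")

    def _segments(self) -> list[tuple[float, float, float]]:
        """(duration, V_start, V_end) per phase, in seconds and m^3."""
        T = self.mode.period
        edv, esv, sv = self.mode.EDV, self.mode.ESV, self.mode.stroke_volume
        v_plateau = edv - self.kick_fraction * sv
        return [
            (self.plateau * T, v_plateau, v_plateau),
            (self.kick * T, v_plateau, edv),
            (self.systole * T, edv, esv),
            (self.diastole * T, esv, v_plateau),
        ]

    def volume(self, t: float) -> float:
        """Ventricular volume at time ``t`` [m^3]."""
        if t < 0:
            raise ValueError("t must be non-negative")
        tau = math.fmod(t, self.mode.period)
        for dur, v0, v1 in self._segments():
            if tau <= dur or dur == 0.0:
                if dur == 0.0:
                    continue
                x = tau / dur
                return v0 + (v1 - v0) * 0.5 * (1.0 - math.cos(math.pi * x))
            tau -= dur
        return self._segments()[-1][2]

    def dvolume(self, t: float) -> float:
        """Analytic dV/dt at time ``t`` [m^3/s]."""
        if t < 0:
            raise ValueError("t must be non-negative")
        tau = math.fmod(t, self.mode.period)
        for dur, v0, v1 in self._segments():
            if tau <= dur or dur == 0.0:
                if dur == 0.0:
                    continue
                x = tau / dur
                return (v1 - v0) * 0.5 * math.pi * math.sin(math.pi * x) / dur
            tau -= dur
        return 0.0


@dataclass(frozen=True)
class ValveLaw:
    """tanh porosity valve with a porosity-to-resistance 0D mapping.

    The porosity P(dp) = P_max [1 + tanh((dp - dp_ref)/s)] is driven by the
    median-filtered *closing* transvalvular pressure difference; the hydraulic
    resistance seen by the flow is R_open + kappa * P.  With the defaults the
    open valve is ~1e6 Pa.s/m^3 and the closed valve ~1e12 Pa.s/m^3.
    """

    P_max: float = 1.0  # porosity scale, dimensionless in 0D
    s: float = 150.0  # tanh slope, Pa
    dp_ref: float = 665.0  # reference closing pressure, Pa (~5 mmHg)
    R_open: float = 1.0e6  # fully-open resistance, Pa.s/m^3
    kappa: float = 5.0e11  # porosity-to-resistance gain, Pa.s/m^3
    w_med: int = 5  # median filter window, samples

    def __post_init__(self) -> None:
        if self.R_open <= 0 or self.s <= 0 or self.kappa < 0:
            raise ConfigurationError("require R_open > 0, s > 0, kappa >= 0")
        if self.w_med < 1 or self.w_med % 2 == 0:
            raise ConfigurationError("w_med must be an odd positive integer")


@dataclass(frozen=True)
class PumpCurve:
    """Quadratic H-Q performance curve dp = a + b Q + c Q^2 at one rotor speed.

    ``clamped`` models the bench protocol where the outflow conduit of a
    stopped pump is clamped: the pump branch carries no flow at all.
    """

    speed: float  # rpm
    a: float = 0.0  # Pa
    b: float = 0.0  # Pa.s/m^3
    c: float = 0.0  # Pa.s^2/m^6
    clamped: bool | None = None

    def __post_init__(self) -> None:
        if self.clamped is None:
            object.__setattr__(self, "clamped", self.speed == 0)
        if self.speed == 0 and not self.clamped:
            raise ConfigurationError("a 0-rpm pump must be clamped")
        if self.speed > 0 and not self.clamped and self.b >= 0:
            raise ConfigurationError("b must be negative for a spinning pump")


#: Experimentally fitted H-Q coefficients per rotor speed [rpm].
PUMP_CURVES: dict[int, PumpCurve] = {
    0: PumpCurve(speed=0, a=0.0, b=0.0, c=0.0, clamped=True),
    8000: PumpCurve(speed=8000, a=1.17e4, b=-7.72e7, c=0.0),
    11000: PumpCurve(speed=11000, a=2.17e4, b=-9.02e7, c=0.0),
}


@dataclass(frozen=True)
class Windkessel3E:
    """3-element Windkessel: series resistance Rs feeding Rp || Cp.

    ``Pc`` is the stored compliance-node pressure and ``Q_prev`` the inflow at
    the previous step (needed by the trapezoidal update).
    """

    Rs: float = 7.8e6  # Pa.s/m^3
    Rp: float = 1.7e8  # Pa.s/m^3
    Cp: float = 1.2e-8  # m^3/Pa
    Pc: float = 1.2e4  # Pa, state
    Q_prev: float = 0.0  # m^3/s, state

    def __post_init__(self) -> None:
        if min(self.Rs, self.Rp, self.Cp) <= 0:
            raise ConfigurationError("Rs, Rp, Cp must be positive")


@dataclass(frozen=True)
class CirculationConfig:
    """Everything needed for one deterministic 0D simulation run."""

    fluid: FluidProperties
    waveform: VolumeWaveform
    mitral: ValveLaw
    aortic: ValveLaw
    pump: PumpCurve
    wk: Windkessel3E
    P_LA: float = 1000.0  # Pa, constant atrial pressure
    dt: float = 0.00428  # s
    n_beats: int = 6
    n_discard: int = 2
    # absolute tolerance on the flow-balance residual, as a fraction of the
    # characteristic flow scale (stroke volume / period)
    residual_rtol: float = 1.0e-6
    bracket: tuple[float, float] = (-1.0e5, 1.0e6)

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ConfigurationError("dt must be positive")
        if not self.n_beats > self.n_discard >= 0:
            raise ConfigurationError("require n_beats > n_discard >= 0")

    @property
    def residual_tol(self) -> float:
        """Absolute flow tolerance [m^3/s] for the pressure solve."""
        mode = self.waveform.mode
        return self.residual_rtol * mode.stroke_volume / mode.period


@dataclass
class SimulationResult:
    """Uniformly sampled series from one run, plus per-step residuals."""

    t: np.ndarray
    V_LV: np.ndarray
    P_LV: np.ndarray
    P_Ao: np.ndarray
    Q_MV: np.ndarray
    Q_AoV: np.ndarray
    Q_VAD: np.ndarray
    residual: np.ndarray
    ok: bool = True
    failed_step: int | None = None


@dataclass(frozen=True)
class QoISet:
    """Scalar quantities of interest for one run [m^3/s]."""

    QAo_avg: float
    QAo_max: float
    QVAD_avg: float
    QVAD_max: float

    @property
    def Qtot_avg(self) -> float:
        return self.QAo_avg + self.QVAD_avg

    def as_dict(self) -> dict[str, float]:
        return {
            "QAo_avg": self.QAo_avg,
            "QAo_max": self.QAo_max,
            "QVAD_avg": self.QVAD_avg,
            "QVAD_max": self.QVAD_max,
            "Qtot_avg": self.Qtot_avg,
        }


QOI_NAMES = ("QAo_avg", "QAo_max", "QVAD_avg", "QVAD_max", "Qtot_avg")


# ---------------------------------------------------------------------------
# elementary operations
# ---------------------------------------------------------------------------


def prescribed_volume(waveform: VolumeWaveform, t: float) -> float:
    """Piston-prescribed ventricular volume at time ``t`` [m^3]."""
    return waveform.volume(t)


def valve_porosity(dp, law: ValveLaw):
    """tanh porosity P = P_max [1 + tanh((dp - dp_ref)/s)].

    ``dp`` is the closing transvalvular pressure difference: large positive
    values close the valve (P -> 2 P_max), large negative open it (P -> 0).
    Accepts scalars or arrays.
    """
    return law.P_max * (1.0 + np.tanh((dp - law.dp_ref) / law.s))


def _valve_resistance(dp_state: float, law: ValveLaw) -> float:
    x = (dp_state - law.dp_ref) / law.s
    return law.R_open + law.kappa * law.P_max * (1.0 + math.tanh(x))


def median_filter(series, w: int):
    """Running median with window ``w`` (odd); edges use a shrunk window."""
    if w < 1 or w % 2 == 0:
        raise ConfigurationError("median filter window must be odd and >= 1")
    x = np.asarray(series, dtype=float)
    if w == 1:
        return x.copy()
    if w > x.size:
        raise ConfigurationError("window exceeds series length")
    h = w // 2
    out = np.empty_like(x)
    for i in range(x.size):
        out[i] = np.median(x[max(0, i - h) : i + h + 1])
    return out


def valve_flow(dp_filtered: float, dp_raw: float, law: ValveLaw) -> float:
    """Flow through a valve [m^3/s].

    ``dp_raw`` is the instantaneous forward pressure difference driving the
    flow; ``dp_filtered`` is the (median-filtered) closing pressure difference
    that sets the porosity state.
    """
    return dp_raw / _valve_resistance(dp_filtered, law)


def pump_flow(dp: float, curve: PumpCurve, clamp_negative: bool = False) -> float:
    """Pump flow for head ``dp`` [Pa] from the quadratic H-Q law.

    For c = 0 this is Q = (dp - a)/b; for c != 0 the root continuous with the
    c -> 0 limit is returned.  Clamped curves carry no flow.
    """
    if curve.clamped:
        return 0.0
    if curve.c == 0.0:
        q = (dp - curve.a) / curve.b
    else:
        # c Q^2 + b Q + (a - dp) = 0, written so the c -> 0 limit is smooth
        disc = 1.0 - 4.0 * curve.c * (curve.a - dp) / (curve.b * curve.b)
        if disc < 0.0:
            raise SolverError(f"no real pump operating point at dp={dp!r}")
        q = 2.0 * (dp - curve.a) / (curve.b * (1.0 + math.sqrt(disc)))
    if clamp_negative and q < 0.0:
        return 0.0
    return q


def windkessel_advance(
    Q_in: float, wk: Windkessel3E, dt: float
) -> tuple[float, Windkessel3E]:
    """One trapezoidal step of the compliance-node ODE Cp dPc/dt = Q - Pc/Rp.

    Returns the proximal pressure P_in = Pc + Q_in * Rs and the updated state.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    tau = wk.Rp * wk.Cp
    k = dt / (2.0 * tau)
    pc_new = (wk.Pc * (1.0 - k) + dt / (2.0 * wk.Cp) * (wk.Q_prev + Q_in)) / (1.0 + k)
    p_in = pc_new + Q_in * wk.Rs
    return p_in, replace(wk, Pc=pc_new, Q_prev=Q_in)


def solve_lv_pressure(
    dVdt: float,
    P_LA: float,
    P_Ao: float,
    R_mitral: float,
    R_aortic: float,
    pump: PumpCurve,
    bracket: tuple[float, float] = (-1.0e5, 1.0e6),
    tol: float = 1.0e-10,
) -> tuple[float, float]:
    """Solve the mass balance for P_LV; returns (P_LV, residual flow).

    The balance is Q_MV(P_LA - P_LV) - Q_AoV(P_LV - P_Ao) - Q_VAD(P_Ao - P_LV)
    = dV/dt with the valve resistances frozen at their filtered state.  The
    balance is strictly decreasing in P_LV so the root is unique; when the
    pump law is linear (c = 0) the solve is closed-form, otherwise a bracketed
    Brent solve is used.
    """

    def residual(p: float) -> float:
        q_mv = (P_LA - p) / R_mitral
        q_ao = (p - P_Ao) / R_aortic
        q_vad = pump_flow(P_Ao - p, pump)
        return q_mv - q_ao - q_vad - dVdt

    if pump.clamped or pump.c == 0.0:
        slope = -(1.0 / R_mitral + 1.0 / R_aortic)
        const = P_LA / R_mitral + P_Ao / R_aortic - dVdt
        if not pump.clamped:
            # -Q_VAD = (P_LV + a - P_Ao)/b
            slope += 1.0 / pump.b
            const += (pump.a - P_Ao) / pump.b
        p_lv = -const / slope
        return p_lv, residual(p_lv)

    from scipy.optimize import brentq

    lo, hi = bracket
    f_lo, f_hi = residual(lo), residual(hi)
    if f_lo * f_hi > 0:
        raise SolverError(
            f"pressure root not bracketed in [{lo}, {hi}]: "
            f"f(lo)={f_lo:.3e}, f(hi)={f_hi:.3e}"
        )
    p_lv = brentq(residual, lo, hi, xtol=1e-9, rtol=8.9e-16)
    return p_lv, residual(p_lv)


# ---------------------------------------------------------------------------
# simulation driver
# ---------------------------------------------------------------------------


def simulate(config: CirculationConfig, seed: int | None = None) -> SimulationResult:
    """Fixed-step march of the 0D circulation over ``n_beats`` beats.

    The run is deterministic for a given config; ``seed`` is reserved for
    optional stochastic extensions and is unused by the core model.  A solver
    failure marks the result failed at the offending step instead of raising,
    so campaign drivers can capture it.
    """
    wf = config.waveform
    T = wf.mode.period
    n_steps = int(round(config.n_beats * T / config.dt)) + 1

    t = np.arange(n_steps) * config.dt
    V = np.empty(n_steps)
    P_LV = np.empty(n_steps)
    P_Ao = np.empty(n_steps)
    Q_MV = np.empty(n_steps)
    Q_AoV = np.empty(n_steps)
    Q_VAD = np.empty(n_steps)
    resid = np.empty(n_steps)

    wk = config.wk
    p_lv = config.P_LA
    p_ao = wk.Pc
    # causal median-filter state: last w raw closing pressure differences
    hist_mv: list[float] = []
    hist_ao: list[float] = []
    w_mv, w_ao = config.mitral.w_med, config.aortic.w_med

    for k in range(n_steps):
        tk = t[k]
        V[k] = wf.volume(tk)
        dvdt = wf.dvolume(tk)

        # valve state from previous pressures (closing-positive convention)
        hist_mv.append(p_lv - config.P_LA)
        hist_ao.append(p_ao - p_lv)
        if len(hist_mv) > w_mv:
            del hist_mv[0]
        if len(hist_ao) > w_ao:
            del hist_ao[0]
        dp_mv_f = _shrunk_median(hist_mv)
        dp_ao_f = _shrunk_median(hist_ao)
        r_mv = _valve_resistance(dp_mv_f, config.mitral)
        r_ao = _valve_resistance(dp_ao_f, config.aortic)

        try:
            p_lv, res = solve_lv_pressure(
                dvdt, config.P_LA, p_ao, r_mv, r_ao, config.pump, config.bracket
            )
        except SolverError:
            return SimulationResult(
                t=t[:k], V_LV=V[:k], P_LV=P_LV[:k], P_Ao=P_Ao[:k],
                Q_MV=Q_MV[:k], Q_AoV=Q_AoV[:k], Q_VAD=Q_VAD[:k],
                residual=resid[:k], ok=False, failed_step=k,
            )
        if abs(res) > config.residual_tol:
            return SimulationResult(
                t=t[:k], V_LV=V[:k], P_LV=P_LV[:k], P_Ao=P_Ao[:k],
                Q_MV=Q_MV[:k], Q_AoV=Q_AoV[:k], Q_VAD=Q_VAD[:k],
                residual=resid[:k], ok=False, failed_step=k,
            )

        q_mv = (config.P_LA - p_lv) / r_mv
        q_ao = (p_lv - p_ao) / r_ao
        q_vad = pump_flow(p_ao - p_lv, config.pump)

        P_LV[k] = p_lv
        P_Ao[k] = p_ao
        Q_MV[k] = q_mv
        Q_AoV[k] = q_ao
        Q_VAD[k] = q_vad
        resid[k] = res

        p_ao, wk = windkessel_advance(q_ao + q_vad, wk, config.dt)

    return SimulationResult(
        t=t, V_LV=V, P_LV=P_LV, P_Ao=P_Ao,
        Q_MV=Q_MV, Q_AoV=Q_AoV, Q_VAD=Q_VAD, residual=resid,
    )


def _shrunk_median(values: list[float]) -> float:
    s = sorted(values)
    n = len(s)
    if n % 2:
        return s[n // 2]
    return 0.5 * (s[n // 2 - 1] + s[n // 2])


def extract_qois(result: SimulationResult, config: CirculationConfig) -> QoISet:
    """Beat-ensemble QoIs over the post-warm-up window.

    Averages are trapezoidal time-averages and maxima pointwise maxima over
    the integer number of beats after discarding ``n_discard`` warm-up beats.
    """
    if not result.ok:
        raise ValueError(f"cannot extract QoIs from a failed run "
                         f"(failed at step {result.failed_step})")
    T = config.waveform.mode.period
    t0, t1 = config.n_discard * T, config.n_beats * T
    sel = (result.t >= t0 - 1e-12) & (result.t <= t1 + 1e-12)
    if sel.sum() < 2:
        raise ValueError("insufficient post-warm-up samples")
    tt = result.t[sel]
    span = tt[-1] - tt[0]

    def avg(x: np.ndarray) -> float:
        return float(np.trapezoid(x[sel], tt) / span)

    return QoISet(
        QAo_avg=avg(result.Q_AoV),
        QAo_max=float(result.Q_AoV[sel].max()),
        QVAD_avg=avg(result.Q_VAD),
        QVAD_max=float(result.Q_VAD[sel].max()),
    )


# ---------------------------------------------------------------------------
# configuration helpers and I/O
# ---------------------------------------------------------------------------


def default_config(
    mode: BeatingMode = MODE_22,
    pump: PumpCurve | int = 8000,
    P_LA: float = 1000.0,
    wk: Windkessel3E | None = None,
    **kwargs,
) -> CirculationConfig:
    """Bench-default configuration; ``pump`` may be a speed key into
    :data:`PUMP_CURVES` or an explicit :class:`PumpCurve`."""
    if isinstance(pump, int):
        pump = PUMP_CURVES[pump]
    return CirculationConfig(
        fluid=FluidProperties(),
        waveform=VolumeWaveform(mode=mode),
        mitral=ValveLaw(),
        aortic=ValveLaw(),
        pump=pump,
        wk=wk if wk is not None else Windkessel3E(),
        P_LA=P_LA,
        **kwargs,
    )


def _config_to_dict(config: CirculationConfig) -> dict:
    wf = config.waveform
    return {
        "fluid": {"rho": config.fluid.rho, "mu": config.fluid.mu},
        "mode": {
            "HR": wf.mode.HR,
            "ESV": wf.mode.ESV,
            "EDV": wf.mode.EDV,
        },
        "waveform": {
            "plateau": wf.plateau,
            "kick": wf.kick,
            "systole": wf.systole,
            "diastole": wf.diastole,
            "kick_fraction": wf.kick_fraction,
        },
        "valves": {
            side: {
                "P_max": v.P_max, "s": v.s, "dp_ref": v.dp_ref,
                "R_open": v.R_open, "kappa": v.kappa, "w_med": v.w_med,
            }
            for side, v in (("mitral", config.mitral), ("aortic", config.aortic))
        },
        "pump": {
            "speed": config.pump.speed, "a": config.pump.a,
            "b": config.pump.b, "c": config.pump.c,
            "clamped": config.pump.clamped,
        },
        "windkessel": {
            "Rs": config.wk.Rs, "Rp": config.wk.Rp,
            "Cp": config.wk.Cp, "Pc": config.wk.Pc,
        },
        "numerics": {
            "P_LA": config.P_LA, "dt": config.dt,
            "n_beats": config.n_beats, "n_discard": config.n_discard,
        },
    }


def _config_from_dict(d: dict) -> CirculationConfig:
    mode = BeatingMode(**d["mode"])
    num = d.get("numerics", {})
    return CirculationConfig(
        fluid=FluidProperties(**d.get("fluid", {})),
        waveform=VolumeWaveform(mode=mode, **d.get("waveform", {})),
        mitral=ValveLaw(**d.get("valves", {}).get("mitral", {})),
        aortic=ValveLaw(**d.get("valves", {}).get("aortic", {})),
        pump=PumpCurve(**d["pump"]),
        wk=Windkessel3E(**d.get("windkessel", {})),
        **num,
    )


def save_config(config: CirculationConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(_config_to_dict(config), fh, sort_keys=False)


def load_config(path) -> CirculationConfig:
    with open(path) as fh:
        return _config_from_dict(yaml.safe_load(fh))


def result_to_frame(result: SimulationResult):
    """Flat table (one row per sample, SI units) for delimited-text output."""
    import pandas as pd

    return pd.DataFrame(
        {
            "t": result.t,
            "V_LV": result.V_LV,
            "P_LV": result.P_LV,
            "P_Ao": result.P_Ao,
            "Q_MV": result.Q_MV,
            "Q_AoV": result.Q_AoV,
            "Q_VAD": result.Q_VAD,
        }
    )
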