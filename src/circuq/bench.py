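"""Virtual measurement bench: a fixture generator for the validation chain.

Emulates the mock-loop measurement chain (clamp-on flow meters on the total
aortic and LVAD lines, catheter pressure sensors, 200 Hz DAQ) so the UQ and
campaign machinery can be exercised without experimental recordings.  Each
sensor applies a per-recording calibration gain drawn within its stated
accuracy, a constant zero offset within its stated maximum, and quantisation
at its resolution.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model import CirculationConfig, QoISet, simulate

__all__ = [
    "SensorSpec",
    "BenchRecording",
    "TS410_20PXL",
    "TS410_10PXL",
    "TRANSPAC_IV",
    "DEFAULT_SENSORS",
    "corrupt",
    "derive_aov_flow",
    "generate_recording",
    "per_beat_qois",
]


@dataclass(frozen=True)
class SensorSpec:
    """Instrument error characteristics.

    ``accuracy`` is the relative (gain-like) full-scale accuracy,
    ``zero_offset`` the maximum constant offset, ``resolution`` the
    quantisation step; ``rate`` the DAQ sampling rate in Hz.
    """

    resolution: float
    zero_offset: float
    accuracy: float
    rate: float = 200.0

    def __post_init__(self) -> None:
        if self.resolution <= 0 or self.rate <= 0:
            raise ValueError("resolution and rate must be positive")
        if self.accuracy < 0 or self.zero_offset < 0:
            raise ValueError("accuracy and zero_offset must be non-negative")


#: Total-aortic-line clamp-on flow meter (m^3/s).
TS410_20PXL = SensorSpec(resolution=8.3e-7, zero_offset=5.0e-9, accuracy=0.10)
#: LVAD-line clamp-on flow meter (m^3/s).
TS410_10PXL = SensorSpec(resolution=1.6e-7, zero_offset=1.0e-9, accuracy=0.10)
#: Catheter pressure transducer (Pa); nominal quantisation at 0.5 mmHg.
TRANSPAC_IV = SensorSpec(resolution=66.665, zero_offset=0.0, accuracy=0.01)

DEFAULT_SENSORS: dict[str, SensorSpec] = {
    "Q_TAo": TS410_20PXL,
    "Q_VAD": TS410_10PXL,
    "P_LV": TRANSPAC_IV,
    "P_Ao": TRANSPAC_IV,
}


def corrupt(signal, spec: SensorSpec, seed=None):
    """Apply the sensor error model: quantize(gain * x + offset, resolution).

    The gain is drawn once per recording from [1 - accuracy, 1 + accuracy] and
    the offset from [-zero_offset, +zero_offset]; both are held constant over
    the recording (calibration-type errors).  Reproducible given ``seed``.
    """
    rng = np.random.default_rng(seed)
    gain = 1.0 + spec.accuracy * rng.uniform(-1.0, 1.0)
    offset = spec.zero_offset * rng.uniform(-1.0, 1.0)
    x = np.asarray(signal, dtype=float)
    return np.round((gain * x + offset) / spec.resolution) * spec.resolution


def derive_aov_flow(Q_TAo, Q_VAD):
    """Aortic valve flow from the two line measurements: Q_AoV = Q_TAo - Q_VAD."""
    a = np.asarray(Q_TAo, dtype=float)
    b = np.asarray(Q_VAD, dtype=float)
    if a.shape != b.shape:
        raise ValueError("Q_TAo and Q_VAD must have equal length")
    return a - b


@dataclass
class BenchRecording:
    """Multi-beat recording of measured channels, with the pre-noise truth."""

    t: np.ndarray
    measured: dict[str, np.ndarray]
    true: dict[str, np.ndarray]
    period: float
    rate: float


def generate_recording(
    config: CirculationConfig,
    specs: dict[str, SensorSpec] | None = None,
    n_beats: int | None = None,
    seed=None,
) -> BenchRecording:
    """Simulate the model and push it through the measurement chain.

    The simulation warm-up (``config.n_discard`` beats) is dropped, the
    remaining beats are resampled on the DAQ grid, and each channel is
    corrupted with its own sensor draw.  The true (pre-noise) series are
    retained for test oracles.
    """
    if specs is None:
        specs = DEFAULT_SENSORS
    if n_beats is not None:
        from dataclasses import replace

        config = replace(config, n_beats=config.n_discard + n_beats)
    res = simulate(config)
    if not res.ok:
        raise RuntimeError(f"simulation failed at step {res.failed_step}")
    T = config.waveform.mode.period
    t0, t1 = config.n_discard * T, config.n_beats * T
    rate = next(iter(specs.values())).rate
    n_out = int(np.floor((t1 - t0) * rate)) + 1
    t_daq = t0 + np.arange(n_out) / rate
    if t_daq[-1] < t1 - 1e-12:  # close the window at the last beat boundary
        t_daq = np.append(t_daq, t1)

    channels = {
        "Q_TAo": res.Q_AoV + res.Q_VAD,
        "Q_VAD": res.Q_VAD,
        "P_LV": res.P_LV,
        "P_Ao": res.P_Ao,
    }
    # linear resampling: the flow series have kinks at valve transitions, so
    # spline resampling would overshoot there
    true = {k: np.interp(t_daq, res.t, v) for k, v in channels.items()}
    ss = np.random.SeedSequence(seed)
    child = ss.spawn(len(true))
    measured = {
        k: corrupt(v, specs[k], seed=child[i])
        for i, (k, v) in enumerate(true.items())
    }
    return BenchRecording(
        t=t_daq - t0, measured=measured, true=true, period=T, rate=rate
    )


def per_beat_qois(recording: BenchRecording, use_true: bool = False) -> list[QoISet]:
    """One QoI sample per full beat of a recording.

    The aortic valve flow is derived from the measured lines; partial trailing
    beats are excluded.  This is the experimental-side dispersion consumed by
    the validation metrics.
    """
    src = recording.true if use_true else recording.measured
    q_aov = derive_aov_flow(src["Q_TAo"], src["Q_VAD"])
    q_vad = src["Q_VAD"]
    t = recording.t
    T = recording.period
    n_full = int(np.floor(t[-1] / T + 1e-9))
    if n_full < 1:
        raise ValueError("recording shorter than one beat")
    out = []
    for i in range(n_full):
        # exact beat boundaries: interpolate the edge samples
        edges = np.array([i * T, (i + 1) * T])
        sel = (t > edges[0]) & (t < edges[1])
        tt = np.concatenate([[edges[0]], t[sel], [edges[1]]])
        qa = np.concatenate([[np.interp(edges[0], t, q_aov)], q_aov[sel],
                             [np.interp(edges[1], t, q_aov)]])
        qv = np.concatenate([[np.interp(edges[0], t, q_vad)], q_vad[sel],
                             [np.interp(edges[1], t, q_vad)]])
        out.append(QoISet(
            QAo_avg=float(np.trapezoid(qa, tt) / T),
            QAo_max=float(qa.max()),
            QVAD_avg=float(np.trapezoid(qv, tt) / T),
            QVAD_max=float(qv.max()),
        ))
    return out


def recording_to_frame(recording: BenchRecording):
    """Delimited-text-ready table: t plus the four measured channels."""
    import pandas as pd

    data = {"t": recording.t}
    data.update(recording.measured)
    return pd.DataFrame(data)
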