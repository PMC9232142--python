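"""Unit and property tests for the 0D circulation model."""

import math
from dataclasses import replace

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from circuq import model
from circuq.model import (
    BeatingMode,
    ConfigurationError,
    MODE_17,
    MODE_22,
    PUMP_CURVES,
    PumpCurve,
    QoISet,
    SimulationResult,
    ValveLaw,
    VolumeWaveform,
    Windkessel3E,
    extract_qois,
    median_filter,
    pump_flow,
    prescribed_volume,
    simulate,
    solve_lv_pressure,
    valve_flow,
    valve_porosity,
    windkessel_advance,
)


class TestBeatingMode:
    def test_fills_missing_edv_from_ef(self):
        m = BeatingMode(HR=60, ESV=180e-6, EF=0.25)
        assert m.EDV == pytest.approx(180e-6 / 0.75)
        assert m.EF == pytest.approx((m.EDV - m.ESV) / m.EDV)

    def test_fills_missing_ef_from_volumes(self):
        assert MODE_22.EF == pytest.approx(50.0 / 230.0)
        assert MODE_17.EF == pytest.approx(36.86 / 216.86, rel=1e-9)

    def test_inconsistent_triple_rejected(self):
        with pytest.raises(ConfigurationError):
            BeatingMode(HR=60, ESV=180e-6, EDV=230e-6, EF=0.22)

    @pytest.mark.parametrize("kwargs", [
        dict(HR=60, ESV=180e-6),            # neither EF nor EDV
        dict(HR=60, ESV=2e-4, EDV=1e-4),    # EDV < ESV
        dict(HR=-5, ESV=1e-4, EF=0.2),      # bad HR
    ])
    def test_invalid_modes_rejected(self, kwargs):
        with pytest.raises(ConfigurationError):
            BeatingMode(**kwargs)


class TestVolumeWaveform:
    def test_bench_mode_volume_bounds(self):
        """End-diastole reaches 230.0e-6 m^3, end-systole 180.0e-6 m^3."""
        wf = VolumeWaveform(mode=MODE_22)
        t = np.linspace(0, MODE_22.period, 20001)
        v = np.array([wf.volume(x) for x in t])
        assert v.max() == pytest.approx(230.0e-6, rel=1e-9)
        assert v.min() == pytest.approx(180.0e-6, rel=1e-9)

    @given(st.floats(min_value=0.0, max_value=20.0))
    @settings(max_examples=50, deadline=None)
    def test_periodicity(self, t):
        wf = VolumeWaveform(mode=MODE_22)
        T = MODE_22.period
        assert wf.volume(t + T) == pytest.approx(wf.volume(t), abs=1e-18)

    def test_derivative_matches_finite_difference(self):
        wf = VolumeWaveform(mode=MODE_17)
        h = 1e-7
        for t in np.linspace(0.01, 2.0, 57):
            fd = (wf.volume(t + h) - wf.volume(t - h)) / (2 * h)
            assert wf.dvolume(t) == pytest.approx(fd, abs=1e-8)

    def test_continuity_at_phase_joints(self):
        wf = VolumeWaveform(mode=MODE_22)
        T = MODE_22.period
        joints = np.cumsum([wf.plateau, wf.kick, wf.systole]) * T
        for tj in joints:
            assert wf.volume(tj - 1e-10) == pytest.approx(wf.volume(tj + 1e-10),
                                                          abs=1e-12)

    def test_bad_fractions_rejected(self):
        with pytest.raises(ConfigurationError):
            VolumeWaveform(mode=MODE_22, plateau=0.5, kick=0.5,
                           systole=0.5, diastole=0.5)

    def test_prescribed_volume_delegates(self):
        wf = VolumeWaveform(mode=MODE_22)
        assert prescribed_volume(wf, 0.3) == wf.volume(0.3)


class TestValveLaw:
    law = ValveLaw()

    def test_reference_point(self):
        assert valve_porosity(self.law.dp_ref, self.law) == pytest.approx(
            self.law.P_max)

    def test_limits(self):
        assert valve_porosity(1e9, self.law) == pytest.approx(2 * self.law.P_max)
        assert valve_porosity(-1e9, self.law) == pytest.approx(0.0, abs=1e-12)

    def test_strictly_increasing_and_bounded(self):
        # within the float-representable transition band around dp_ref
        dps = self.law.dp_ref + np.linspace(-2000, 2000, 501)
        p = valve_porosity(dps, self.law)
        assert np.all(np.diff(p) > 0)
        assert np.all(p > 0) and np.all(p < 2 * self.law.P_max)

    def test_open_limit_is_ohm_law(self):
        q = valve_flow(-1e4, 500.0, self.law)
        assert q == pytest.approx(500.0 / self.law.R_open, rel=1e-6)

    def test_zero_dp_zero_flow(self):
        assert valve_flow(-1e4, 0.0, self.law) == 0.0

    def test_closed_limit_bound(self):
        # fully closed: |Q| <= dp / (R_open + kappa * 2 P_max)
        dp = 8000.0
        q = valve_flow(1e6, dp, self.law)
        lower_r = self.law.R_open + self.law.kappa * 2 * self.law.P_max
        assert abs(q) <= dp / lower_r * (1 + 1e-9)
        # and matches direct evaluation of the porosity-resistance mapping
        direct = dp / (self.law.R_open + self.law.kappa * valve_porosity(1e6, self.law))
        assert q == pytest.approx(direct)

    def test_even_window_rejected(self):
        with pytest.raises(ConfigurationError):
            ValveLaw(w_med=4)


class TestMedianFilter:
    def test_constant_unchanged(self):
        x = np.full(11, 3.3)
        assert np.array_equal(median_filter(x, 5), x)

    def test_spike_rejection(self):
        assert np.array_equal(median_filter([0, 0, 9, 0, 0], 3),
                              np.zeros(5))

    def test_window_one_is_identity(self):
        x = np.array([5.0, -1.0, 2.0])
        assert np.array_equal(median_filter(x, 1), x)

    def test_even_window_raises(self):
        with pytest.raises(ConfigurationError):
            median_filter([1.0, 2.0, 3.0], 2)

    def test_edges_shrink_window(self):
        out = median_filter([1.0, 100.0, 2.0, 100.0, 3.0], 3)
        assert out[0] == 50.5  # median of first two
        assert out[2] == 100.0


class TestPumpFlow:
    def test_zero_flow_at_shutoff_head(self):
        c8 = PUMP_CURVES[8000]
        assert pump_flow(c8.a, c8) == 0.0

    def test_zero_head_flow(self):
        c8 = PUMP_CURVES[8000]
        assert pump_flow(0.0, c8) == pytest.approx(1.17e4 / 7.72e7)

    def test_clamped_curve_never_flows(self):
        c0 = PUMP_CURVES[0]
        for dp in (-1e4, 0.0, 1e4, 1e6):
            assert pump_flow(dp, c0) == 0.0

    @pytest.mark.parametrize("speed", [8000, 11000])
    def test_monotone_non_increasing_in_head(self, speed):
        curve = PUMP_CURVES[speed]
        dps = np.linspace(-2e4, 5e4, 100)
        qs = [pump_flow(dp, curve) for dp in dps]
        assert all(a >= b for a, b in zip(qs, qs[1:]))

    def test_quadratic_root_continuous_with_linear_limit(self):
        base = PUMP_CURVES[8000]
        quad = replace(base, c=1e4)
        for dp in (-5e3, 0.0, 5e3, 1.1e4):
            assert pump_flow(dp, quad) == pytest.approx(pump_flow(dp, base),
                                                        rel=1e-2)

    def test_no_real_root_raises(self):
        curve = PumpCurve(speed=9000, a=1e4, b=-1e3, c=1e12)
        with pytest.raises(model.SolverError):
            pump_flow(-1e9, curve)

    def test_zero_speed_must_be_clamped(self):
        with pytest.raises(ConfigurationError):
            PumpCurve(speed=0, clamped=False)


class TestWindkessel:
    def test_rest_state(self):
        wk = Windkessel3E(Pc=0.0)
        for _ in range(100):
            p, wk = windkessel_advance(0.0, wk, 0.004)
            assert p == 0.0

    def test_constant_inflow_steady_state(self):
        """Pc -> Q Rp, so P_in -> Q (Rs + Rp) = 1.778e4 Pa at Q = 1e-4."""
        wk = Windkessel3E(Rs=7.8e6, Rp=1.7e8, Cp=1.2e-8, Pc=0.0)
        q = 1e-4
        p = 0.0
        for _ in range(20000):  # 80 s >> tau = 2.04 s
            p, wk = windkessel_advance(q, wk, 0.004)
        assert p == pytest.approx(q * (7.8e6 + 1.7e8), rel=1e-6)
        assert p == pytest.approx(1.778e4, rel=1e-3)

    def test_free_decay_time_constant(self):
        wk = Windkessel3E(Pc=1.0e4, Q_prev=0.0)
        tau = wk.Rp * wk.Cp
        dt = 0.002
        state = wk
        t, log_pc = [], []
        for k in range(1, 1001):
            _, state = windkessel_advance(0.0, state, dt)
            t.append(k * dt)
            log_pc.append(math.log(state.Pc))
        slope = np.polyfit(t, log_pc, 1)[0]
        assert -1.0 / slope == pytest.approx(tau, rel=1e-4)


class TestSolveLvPressure:
    def test_equilibrium(self):
        p, res = solve_lv_pressure(0.0, 1000.0, 1000.0, 1e6, 1e6,
                                   PUMP_CURVES[0])
        assert p == pytest.approx(1000.0)
        assert abs(res) < 1e-15

    def test_single_open_path_algebra(self):
        """With only the mitral path conducting, P_LV = P_LA - R dV/dt."""
        r_mv = 2e6
        p, _ = solve_lv_pressure(1e-4, 1000.0, 5000.0, r_mv, 1e18,
                                 PUMP_CURVES[0])
        assert p == pytest.approx(1000.0 - r_mv * 1e-4, rel=1e-9)

    @pytest.mark.parametrize("pump", [
        PUMP_CURVES[0],
        PUMP_CURVES[8000],
        PUMP_CURVES[11000],
        replace(PUMP_CURVES[8000], c=2e8),
    ])
    def test_agrees_with_bisection_oracle(self, pump):
        rng = np.random.default_rng(42)
        for _ in range(20):
            dvdt = rng.uniform(-3e-4, 3e-4)
            p_la = rng.uniform(200, 2000)
            p_ao = rng.uniform(5e3, 3e4)
            r_mv = 10 ** rng.uniform(6, 8.5)
            r_ao = 10 ** rng.uniform(6, 8.5)

            def f(p):
                return ((p_la - p) / r_mv - (p - p_ao) / r_ao
                        - pump_flow(p_ao - p, pump) - dvdt)

            lo, hi = -1e5, 1e6
            for _ in range(200):  # plain bisection oracle
                mid = 0.5 * (lo + hi)
                if f(lo) * f(mid) <= 0:
                    hi = mid
                else:
                    lo = mid
            oracle = 0.5 * (lo + hi)
            p, res = solve_lv_pressure(dvdt, p_la, p_ao, r_mv, r_ao, pump)
            assert p == pytest.approx(oracle, rel=1e-6, abs=1e-4)

    def test_unbracketed_root_raises(self):
        pump = replace(PUMP_CURVES[8000], c=2e8)
        with pytest.raises(model.SolverError):
            solve_lv_pressure(1.0, 0.0, 0.0, 1e30, 1e30, pump,
                              bracket=(-1.0, 1.0))


class TestSimulate:
    def test_dead_rig_is_quiescent(self, frozen_ventricle_cfg):
        res = simulate(frozen_ventricle_cfg)
        assert res.ok
        for series in (res.Q_MV, res.Q_AoV, res.Q_VAD, res.P_LV):
            assert np.allclose(series, 0.0, atol=1e-15)

    def test_mass_conservation_every_step(self, default_cfg, default_result):
        assert default_result.ok
        assert np.abs(default_result.residual).max() <= default_cfg.residual_tol

    def test_beat_integral_conservation(self, settled_cfg):
        """Integral of net inflow over one beat equals the volume change."""
        res = simulate(settled_cfg)
        T = settled_cfg.waveform.mode.period
        sel = (res.t >= 7 * T) & (res.t <= 8 * T)
        net = res.Q_MV[sel] - res.Q_AoV[sel] - res.Q_VAD[sel]
        lhs = np.trapezoid(net, res.t[sel])
        dv = res.V_LV[sel][-1] - res.V_LV[sel][0]
        assert lhs == pytest.approx(dv, abs=2e-7)

    def test_periodic_steady_state_flow_balance(self, settled_cfg):
        """Beat-averaged inflow matches beat-averaged outflow once settled."""
        res = simulate(settled_cfg)
        T = settled_cfg.waveform.mode.period
        sel = (res.t >= 6 * T) & (res.t <= 10 * T)
        q_in = np.trapezoid(res.Q_MV[sel], res.t[sel])
        q_out = np.trapezoid(res.Q_AoV[sel] + res.Q_VAD[sel], res.t[sel])
        assert q_in == pytest.approx(q_out, rel=0.02)

    def test_determinism_bit_identical(self, default_cfg):
        q1 = extract_qois(simulate(default_cfg), default_cfg)
        q2 = extract_qois(simulate(default_cfg), default_cfg)
        assert q1 == q2

    def test_monotone_pump_influence(self):
        """Raising the shutoff head a_VAD steals flow from the aortic valve."""
        qao, qvad = [], []
        for a in (0.8e4, 1.17e4, 1.7e4, 2.17e4):
            pump = replace(PUMP_CURVES[8000], a=a)
            cfg = model.default_config(pump=pump)
            q = extract_qois(simulate(cfg), cfg)
            qao.append(q.QAo_avg)
            qvad.append(q.QVAD_avg)
        assert all(x >= y for x, y in zip(qao, qao[1:]))
        assert all(x <= y for x, y in zip(qvad, qvad[1:]))

    def test_positive_ef_hr_influence(self):
        qtot_ef = []
        for ef in (0.12, 0.22, 0.32):
            cfg = model.default_config(mode=BeatingMode(HR=68.42, ESV=180e-6, EF=ef))
            qtot_ef.append(extract_qois(simulate(cfg), cfg).Qtot_avg)
        assert qtot_ef == sorted(qtot_ef)
        qtot_hr = []
        for hr in (50.0, 70.0, 95.0):
            cfg = model.default_config(mode=BeatingMode(HR=hr, ESV=180e-6, EDV=230e-6))
            qtot_hr.append(extract_qois(simulate(cfg), cfg).Qtot_avg)
        assert qtot_hr == sorted(qtot_hr)


class TestExtractQois:
    @staticmethod
    def _result_from_series(t, q_aov, q_vad):
        z = np.zeros_like(t)
        return SimulationResult(t=t, V_LV=z, P_LV=z, P_Ao=z, Q_MV=z,
                                Q_AoV=q_aov, Q_VAD=q_vad, residual=z)

    def test_constant_series(self, default_cfg):
        T = default_cfg.waveform.mode.period
        t = np.arange(0, default_cfg.n_beats * T + default_cfg.dt,
                      default_cfg.dt)
        res = self._result_from_series(t, np.full_like(t, 3e-5),
                                       np.zeros_like(t))
        q = extract_qois(res, default_cfg)
        assert q.QAo_avg == pytest.approx(3e-5)
        assert q.QAo_max == pytest.approx(3e-5)

    def test_clamped_pump_zero_vad_qois(self):
        cfg = model.default_config(pump=0)
        q = extract_qois(simulate(cfg), cfg)
        assert q.QVAD_avg == 0.0
        assert q.QVAD_max == 0.0

    def test_half_sine_pulse_closed_form(self, default_cfg):
        """Half-sine of amplitude A and duty f: max A, average 2 A f / pi."""
        T = default_cfg.waveform.mode.period
        t = np.arange(0, default_cfg.n_beats * T, T / 4000)
        A, f = 2.0e-4, 0.3
        phase = (t % T) / T
        q_aov = np.where(phase < f, A * np.sin(np.pi * phase / f), 0.0)
        res = self._result_from_series(t, q_aov, np.zeros_like(t))
        q = extract_qois(res, default_cfg)
        assert q.QAo_max == pytest.approx(A, rel=1e-5)
        assert q.QAo_avg == pytest.approx(2 * A * f / np.pi, rel=1e-3)

    def test_qtot_is_sum(self, default_qois):
        assert default_qois.Qtot_avg == (default_qois.QAo_avg
                                         + default_qois.QVAD_avg)
        assert default_qois.QAo_max >= default_qois.QAo_avg
        assert default_qois.QVAD_max >= default_qois.QVAD_avg

    def test_failed_run_rejected(self, default_cfg):
        res = SimulationResult(*(np.zeros(0),) * 8, ok=False, failed_step=7)
        with pytest.raises(ValueError, match="failed"):
            extract_qois(res, default_cfg)


class TestConfigIO:
    def test_yaml_roundtrip(self, tmp_path, default_cfg):
        path = tmp_path / "cfg.yaml"
        model.save_config(default_cfg, path)
        again = model.load_config(path)
        assert again.pump == default_cfg.pump
        assert again.wk == default_cfg.wk
        assert again.waveform.mode.EDV == default_cfg.waveform.mode.EDV
        q1 = extract_qois(simulate(default_cfg), default_cfg)
        q2 = extract_qois(simulate(again), again)
        assert q1 == q2

    def test_result_table_columns(self, default_result):
        df = model.result_to_frame(default_result)
        assert list(df.columns) == ["t", "V_LV", "P_LV", "P_Ao",
                                    "Q_MV", "Q_AoV", "Q_VAD"]
        assert len(df) == len(default_result.t)
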