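# circuq

A desk-scale, lumped-parameter (0D) model of a left ventricle supported by a
continuous-flow left ventricular assist device (LVAD), together with the
verification, validation and uncertainty-quantification (VVUQ) machinery
needed to assess it: analytic flow oracles and grid-convergence utilities,
Latin-hypercube sensitivity analysis with polynomial-chaos total Sobol
indices, Minkowski-L1 / p-box validation metrics, a campaign orchestrator
with failure capture and restart, and a pump-speed ramp-study application.

## Who this is for

LVAD speed selection balances two competing clinical requirements: the pump
must provide a cardiac output compatible with life
(Q̄_tot = Q̄_Ao + Q̄_VAD > 7×10⁻⁵ m³/s ≈ 4.2 L/min for an average body
surface area), while leaving enough flow through the aortic valve that it
still opens (Q̄_Ao > 5×10⁻⁶ m³/s ≈ 0.3 L/min) — a permanently closed valve
promotes aortic insufficiency and thrombosis. `circuq` reproduces, at the
lumped level, the working principle of a piston-driven mock circulation loop
used to study this trade-off, and wraps it in the statistical tooling needed
to say how much the predictions can be trusted.

## The model

A piston prescribes the ventricular volume V(t) between the end-systolic and
end-diastolic volumes (linked to the ejection fraction by
EF = (EDV − ESV)/EDV). Because volume is prescribed, the left-ventricular
pressure P_LV is the single unknown closing the per-step mass balance

    Q_MV − Q_AoV − Q_VAD = dV/dt.

The flow paths are:

* **Valves** — porosity P(Δp) = P_max [1 + tanh((Δp − Δp_ref)/s)] driven by
  the median-filtered *closing* transvalvular pressure difference, mapped in
  0D to a hydraulic resistance R = R_open + κ·P. Large closing Δp ⇒ valve
  shut (R ≈ 10¹² Pa·s/m³); forward Δp ⇒ open (R = R_open).
* **Pump** — the quadratic H-Q performance curve Δp = a + bQ + cQ², with the
  experimentally fitted coefficients per rotor speed (a = 1.17×10⁴ Pa,
  b = −7.72×10⁷ Pa·s/m³ at 8 krpm; a = 2.17×10⁴, b = −9.02×10⁷ at 11 krpm;
  a clamped zero-flow branch at 0 rpm).
* **Afterload** — a 3-element Windkessel (R_s = 7.8×10⁶, R_p = 1.7×10⁸
  Pa·s/m³, C_p = 1.2×10⁻⁸ m³/Pa) advanced with the trapezoidal rule.
* **Preload** — a constant atrial pressure P_LA.

Everything is strict SI internally; the default time step is 0.00428 s.

## Worked example

```python
from circuq import default_config, simulate, extract_qois

for speed in (0, 8000, 11000):
    cfg = default_config(pump=speed)          # 22%@68.42bpm beating mode
    qoi = extract_qois(simulate(cfg), cfg)
    print(speed, f"QAo_avg={qoi.QAo_avg:.3e}", f"QVAD_avg={qoi.QVAD_avg:.3e}",
          f"Qtot_avg={qoi.Qtot_avg:.3e}")
```

prints

```
0 QAo_avg=5.523e-05 QVAD_avg=0.000e+00 Qtot_avg=5.523e-05
8000 QAo_avg=1.374e-05 QVAD_avg=5.006e-05 Qtot_avg=6.380e-05
11000 QAo_avg=3.166e-06 QVAD_avg=9.338e-05 Qtot_avg=9.654e-05
```

Read: with the pump off (clamped outflow) the failing ventricle produces
3.3 L/min, all through the aortic valve. At 8 krpm the pump carries most of
the output but the total (3.8 L/min) still misses the 4.2 L/min requirement;
at 11 krpm the total is ample (5.8 L/min) but the mean aortic-valve flow
(0.19 L/min) drops below the 0.3 L/min opening threshold — the two clinical
criteria bound the feasible speed window from opposite sides.

The same study over a speed ramp:

```python
from circuq import ramp
grid = ramp.run_ramp(HRs=(68.42,), EFs=(50/230,))
print(ramp.speed_window(grid))
```

A command-line interface mirrors the library:
`circuq simulate`, `circuq verify`, `circuq sa`, `circuq uq`, `circuq ramp`
and `circuq campaign run` (see `circuq --help`).

## Layout

* `circuq.model` — the 0D circulation simulator and its configuration types
* `circuq.verification` — Poiseuille/Womersley oracles, RMSE, observed order, GCI
* `circuq.sensitivity` — LHS, Pearson, PCE surrogate, total Sobol indices, screening
* `circuq.uq` — validation points, ECDF/p-box Minkowski-L1 metrics, forward propagation
* `circuq.bench` — virtual measurement bench (sensor-error fixture generator)
* `circuq.campaign` — plan/execute/resume orchestration with failure capture
* `circuq.ramp` — ramp protocol, clinical criteria, feasible speed windows

See `docs/methods.md` for the modelling assumptions, parameter choices and
known limitations.
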