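# Methods

## Model

`circuq.model` is a lumped-parameter (0D) representation of a piston-driven
mock circulation loop: a silicone left ventricle immersed in a sealed tank,
filled from a constant-pressure atrial reservoir through a mitral
bioprosthesis, ejecting through an aortic bioprosthesis into a tuned systemic
circuit, with a continuous-flow pump drawing from the apex to the ascending
aorta. The piston prescribes the ventricular volume irrespective of the
internal pressure, so the model state reduces to the Windkessel
compliance-node pressure, and the left-ventricular pressure is obtained at
every step from the algebraic mass balance

    Q_MV(P_LA − P_LV) − Q_AoV(P_LV − P_Ao) − Q_VAD(P_Ao − P_LV) = dV/dt.

Assumptions inherited from the rig: no Frank–Starling response (the volume
waveform does not react to loading), no beat-to-beat variability, constant
atrial pressure, rigid connecting lines, Newtonian blood analogue
(ρ = 1100 kg/m³, μ = 3.72×10⁻³ Pa·s — the fluid properties enter the 0D
balance only through the calibrated resistances, and are carried for the
verification oracles).

### Volume waveform

The piston waveform is not published; the generator uses four raised-cosine
phases per beat, in order: diastasis plateau just below EDV, atrial kick
completing the fill to EDV, systolic ejection to ESV, and passive diastolic
filling back to the plateau level. Defaults: plateau 0.15, kick 0.15,
systole 0.30, diastole 0.40 of the period; kick amplitude 0.10 of the stroke
volume. Raised cosines make V(t) continuously differentiable, so dV/dt is
available in closed form. All fractions are configurable; the minimum and
maximum over a period are exactly ESV and EDV by construction.

The two named beating modes are built from the printed volumes
(ESV = 180.0×10⁻⁶ m³ with EDV = 230.0×10⁻⁶ m³ at 68.42 bpm, and
EDV = 216.86×10⁻⁶ m³ at 61.18 bpm); the ejection fraction is derived from
the volumes (21.74% and 17.00%), since the constructor enforces
EF = (EDV − ESV)/EDV to 10⁻⁹. When EF itself is the sampled input (UQ, ramp),
ESV is held at the silicone-ventricle value and EDV = ESV/(1 − EF).

### Valves

The tanh porosity law P(Δp) = P_max [1 + tanh((Δp − Δp_ref)/s)] is driven by
the *closing* pressure difference per valve (mitral: P_LV − P_LA; aortic:
P_Ao − P_LV), median-filtered over the last `w_med` = 5 solver samples to
reject transient spikes. In 3D this porosity is a volumetric drag; in 0D it
maps to an additive hydraulic resistance R(Δp) = R_open + κ·P(Δp), which
preserves the open/closed switching semantics with one calibration constant.

Calibration (not published; chosen once on hydraulic grounds):

| parameter | value | rationale |
|---|---|---|
| R_open | 10⁶ Pa·s/m³ | a few mmHg drop at peak physiological flow |
| κ·2P_max | 10¹² Pa·s/m³ | closed-valve leak < 10⁻⁸ m³/s at 10⁴ Pa |
| Δp_ref | 665 Pa (5 mmHg) | valve effectively open at zero closing Δp |
| s | 150 Pa | smooth but decisive transition (≈ 4.4 s-widths to Δp_ref) |

Because the porosity state is evaluated from the filtered history (previous
steps), the per-step balance sees frozen valve resistances; with the linear
pump law this makes the P_LV solve closed-form, and strictly monotone (hence
uniquely rooted) in general.

### Pump

Δp = a + bQ + cQ² per rotor speed; all published fits have c = 0 and b < 0.
For c ≠ 0 the root continuous with the c → 0 limit is selected via the
citardauq form Q = 2(Δp − a)/(b(1 + √(1 − 4c(a − Δp)/b²))). A 0-rpm pump is
*clamped* (zero flow at any head), matching the bench protocol where the
outflow conduit of a stopped pump is tied off to prevent backflow. Speeds
between the measured 8 k and 11 k curves (and the 12 k ramp top) interpolate
(a, b) linearly in speed and are flagged in ramp reports.

### Afterload and integration

The 3-element Windkessel (R_s series into R_p ∥ C_p) obeys
C_p dP_c/dt = Q_in − P_c/R_p and is advanced with the implicit trapezoidal
rule (second order; verified by the dt-refinement study in
`verification.windkessel_dt_study`, observed order 2.000). The LV ↔
Windkessel coupling is explicit: the P_LV solve uses the aortic pressure
from the previous step, which is stable here because the Windkessel time
constant (≈ 2 s) is three orders above the step. The default dt = 0.00428 s
is the historical acquisition period of the reference rig; note it is close
to, but not exactly, the 200 Hz DAQ period (0.005 s).

Default run length: 6 beats with 2 discarded as warm-up. The Windkessel
transient decays with τ = R_p·C_p ≈ 2 s, so a small (≈ 1–2%) beat-to-beat
drift survives the default warm-up; tests of strict periodicity use longer
runs (10 beats, 6 discarded). QoIs (beat-averaged and maximum aortic and
pump flows) are computed by trapezoidal time-averages and pointwise maxima
over the retained integer number of beats; Q̄_tot = Q̄_Ao + Q̄_VAD by
construction. The pressure solve records its residual each step; runs exceed
ing the tolerance (10⁻⁶ of the stroke-volume-per-period flow scale) are
marked failed with the step index rather than raising, so campaign drivers
can capture them.

## Verification utilities

Poiseuille (u = G(R² − r²)/4μ) and Womersley (complex Bessel-J₀ solution
with i^{3/2} = e^{i3π/4}) profiles serve as analytic oracles; the Womersley
implementation reduces to quasi-steady Poiseuille below α = 0.1 (≤ 1% RMS).
Observed order of convergence uses the two-level error formula against an
exact solution or the three-level Richardson formula on solution values; the
GCI uses the standard 95%-confidence safety factors (1.25 for three or more
grids, 3.0 for two). The module verifies the package's own integrator (dt
refinement on the Windkessel ODE); it does not attempt to reproduce
mesh-convergence figures of any 3D solver, which depend on that solver's
discretisation.

## Sensitivity analysis

Inputs are classified deterministic / aleatory / epistemic; the shared input
space spans HR [40, 120] bpm, P_LA [0.5, 1.5] kPa, EF [0.10, 0.35],
R_s [5, 20]×10⁶, R_p [50, 200]×10⁶ Pa·s/m³, C_p [5, 20]×10⁻⁷ m³/Pa, and the
pump coefficients a ∈ [2.5, 100]×10³ Pa, b ∈ −[0.5, 5]×10⁸ Pa·s/m³ (ranges
bracketing the fitted 8 k/11 k coefficients, each spanning roughly an order
of magnitude). Sampling is Latin hypercube (`scipy.stats.qmc`). Local
sensitivity is Pearson's ρ; global sensitivity fits a total-degree
polynomial chaos expansion on orthonormal Legendre polynomials by least
squares (default order 5; the sample count must reach the basis size — with
8 inputs a degree-5 basis has 1287 terms) and reports total Sobol indices
two ways: exactly from the PCE coefficients, and by Saltelli/Jansen sampling
of the surrogate with a scrambled Sobol' sequence (default 5000 base
samples). Screening drops an input whose total index is below 0.25; the
default rule requires it to be below threshold for *every* QoI (the
alternative any-QoI rule is exposed, since either reading is defensible).

One practical note: over this wide input space the pump coefficients
dominate the output variance, so low-n marginal correlations of weak inputs
(HR on Q̄_tot) are noisy at n = 100. The sign checks therefore use paired
ceteris-paribus contrasts (re-running the model with only EF or HR moved),
which estimate the partial-derivative sign directly; pointwise the model's
Q̄_tot is non-decreasing in both EF and HR (flat in pump-dominated corners).

## Validation metrics and forward UQ

The six validation points pair two beating conditions (EF/HR at the bench
settings ± 10%) with three pump speeds; the 8 k/11 k H-Q coefficient ranges
come from the fit-uncertainty analysis (a ∈ [10.91, 12.66]×10³ and
[19.64, 23.77]×10³ Pa; b ∈ [−7.90, −7.53]×10⁷ and [−9.80, −8.24]×10⁷
Pa·s/m³), and the 0-rpm coefficients are deterministically zero — giving
identically zero pump-flow QoIs (a Dirac ECDF). 50 LHS samples per point are
propagated through the model (300 runs).

The measured QoI carries a ± 10% band. The Minkowski-L1 metric is the area
between CDFs, in the QoI's units: MN^u integrates |F_sim − F_uniform| with
the band read as a uniform distribution, by exact piecewise integration
(ECDF constant, uniform CDF linear between breakpoints, split at interior
crossings); the p-box bounds MN⁻/MN⁺ are distances to unit steps at the band
limits, which collapse to E|X − L|. Both agree with adaptive quadrature to
10⁻⁹ in tests. Metrics require ≥ 80% successful runs per point (configurable),
otherwise the point is flagged.

## Virtual bench

`circuq.bench` emulates the measurement chain so the validation machinery is
testable without recordings: per-channel clamp-on flow meters (total aortic:
resolution 8.3×10⁻⁷ m³/s, max zero offset 5×10⁻⁹, accuracy 10%; pump line:
1.6×10⁻⁷, 1.0×10⁻⁹, 10%) and pressure transducers, sampled at 200 Hz. The
stated "absolute accuracy" is modelled as a per-recording multiplicative
gain (calibration-type error, drawn once per recording), the zero offset as
a per-recording constant, and the resolution as quantisation; whether the
10% is gain-like or additive is not documented, so the choice is
configurable. The aortic valve flow is derived as Q_AoV = Q_TAo − Q_VAD,
exactly as on the rig. The pre-noise series are retained for test oracles.

What the virtual bench does *not* emulate: flow disturbances around the
meters, user/setup variability, silicone-wall mechanics, or drift — so tests
passing against it demonstrate that the statistical chain (ECDFs, bands,
metrics, campaign plumbing) is correct, not that the model matches a
physical rig. Resampling a kinked flow signal onto the 200 Hz grid carries
an inherent per-beat error of up to ~1% on peak QoIs (the sampling comb
drifts across beats); round-trip tests therefore align the DAQ grid with the
solver grid, where the chain is transparent to < 0.5%.

## Campaign orchestration

Plans are deterministic given (points, n, seed): per-run seeds derive from
the campaign seed by a splitmix64 counter. Execution is local and
sequential by default (a process pool is available); every run is attempted,
failures are captured as records with diagnostics, and optional retries
re-attempt before recording failure. Results append to a tab-separated
journal as they finish; `resume` keeps `ok` records, re-executes the rest,
and — the model being deterministic — reproduces the uninterrupted final
table byte-for-byte. Queue submission layers are intentionally out of scope;
the executor interface is a plain callable so one could be added.

## Ramp study

The ramp protocol steps the pump from 8000 to 12000 rpm in 400 rpm
increments (11 speeds). Criteria are strict: aortic valve opening
Q̄_Ao > 5×10⁻⁶ m³/s (0.3 L/min) and cardiac output
Q̄_tot > 7×10⁻⁵ m³/s (4.2 L/min, i.e. a 2.2 L/min/m² cardiac index at
BSA 1.9 m²; the desired output scales linearly with BSA). The feasible
window per (HR, EF) is the maximal contiguous run of speeds meeting both; on
this model the lower bound comes from the output criterion and the upper
bound from valve opening, matching the clinical picture. An empty window is
a result, not an error.

## Numerical choices and degenerate inputs

* Pressure solve: closed form when the pump law is linear or clamped;
  bracketed Brent otherwise on [−10⁵, 10⁶] Pa, failure reported with the
  bracket residuals.
* Median filter: shrinking window at edges; window 1 is the identity; even
  windows rejected.
* ECDF: right-continuous; a single sample is a unit step.
* Degenerate (zero-width) measurement bands reduce MN^u to the step distance
  E|X − L|; negative measured values order the band endpoints.
* Quadratic pump curves with no real operating point raise a solver error
  rather than returning a complex root.
* GCI with r^p = 1, zero-norm RMSE references, and non-bracketed pressure
  roots are explicit errors.

## Problem sizes used by the test suite and acceptance script

Simulations run 6 beats (2 warm-up) at dt = 0.00428 s (≈ 1200 steps,
~10 ms each); the sensitivity sweep uses 100 LHS samples plus 2×20 paired
contrasts; the validation campaign 6 × 50 = 300 runs; Sobol-index tests use
2000 fitting samples and 5000 surrogate evaluations. These sizes make the
whole analysis reproducible on a laptop in seconds while leaving every
statistical check comfortably resolved.

## Known limitations

* The 0D valve calibration constants are hydraulically motivated, not fitted
  to the rig; absolute flow magnitudes should be read as plausible, not
  calibrated.
* The explicit LV↔Windkessel coupling limits dt to well below the Windkessel
  time constant (amply satisfied at the default).
* No Frank–Starling mechanism, by design (the rig has none): atrial pressure
  and arterial impedance therefore have unrealistically small influence
  compared to a human ventricle.
* Pump curves between measured speeds are linear interpolations; the
  12 krpm ramp top is an extrapolation and is flagged as such.
* The model predicts flows only; septal position, regurgitation and intra-LV
  flow structure are outside the 0D state.
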