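# Methods

`lvadhemo` predicts shear-induced hemolysis of a continuous-flow left
ventricular assist device (LVAD) from its operating point alone — no CFD.
This note describes the models, their assumptions, the numeric choices, and
what the synthetic-data generators do and do not emulate.

## Hemolysis rate index and the modified power law

In vitro hemolysis is quantified by the hemolysis rate index

HRI [%·mL/h] = (ΔpfHb / Hb) · 100 · (V / ΔT) · (100 − HCT) / 100,

the hourly rise of plasma-free hemoglobin normalized to total hemoglobin
and hematocrit, scaled by the loop volume V so results are comparable
across circuits. pfHb is measured in mg/dL and Hb in g/dL; the
implementation converts explicitly (×1000) before forming the ratio. V and
HCT of each interval are the interval-start measurements — the definition
leaves the endpoint open, so this convention is declared and tested.
Negative intervals (assay noise) are kept in the mean but flagged.

The static model is a power law in the pump operating point,

HRI / H̄RI = c₂ · (Q/Q̄)^a₂ · (n/n̄)^b₂,

with scaling constants (H̄RI, Q̄, n̄) = (43.22 %·mL/h, 4.65 L/min, 7415 rpm)
and fitted parameters c₂ = 0.740, a₂ = −0.394, b₂ = 5.45 for the Sputnik1
axial pump. Low flow means long exposure (a₂ < 0); speed drives shear
steeply (b₂ ≈ 5.5). One printed source lists H̄RI in %·mL/min; the package
uses %·mL/h throughout, consistent with the HRI definition and the fit
statistics.

Several pumps of the same type differ in absolute hemolysis level
(specimen-to-specimen variation); before fitting, each device's HRI values
are standardized — divided by the device mean and multiplied by H̄RI — which
collapses proportional devices onto a single surface without changing the
relative pattern.

### Robust fitting

(c₂, a₂, b₂) are fitted on the linear HRI scale by iteratively reweighted
nonlinear least squares with bisquare weights (tuning constant 4.685, scale
from the residual MAD), started from an ordinary log–log regression.
Implementation notes:

* When the MAD degenerates to ~0 (most points fitted exactly, e.g. an
  isolated gross outlier in otherwise clean data), the scale falls back to
  the mean absolute residual; a pure "perfect-fit" shortcut would otherwise
  enter a weight limit cycle.
* Convergence is declared at a relative parameter move < 1e−5; the cap is
  100 reweighting iterations. Because each reweighting step contains a full
  nonlinear (Levenberg–Marquardt) solve, contraction near the fixed point
  is slower than in linear IRLS, and a 50-iteration cap occasionally falls
  just short on noisy 60-point designs.
* RMSE and R² are reported on the standardized data with unit weights (the
  weighting convention behind published single-number fit statistics is
  generally unstated; unit weights are the conservative choice).

## Lagrangian dynamics

To use the static law under time-varying speed and flow, damage is
accumulated in discrete particles advected through the impeller region
(blood volume Vi = 7.04 mL, path length li = 55 mm for the Sputnik1).
Substituting the exposure time t_exp = Vi/Q into the power law gives the
reduced form HRI = ĉ₂ · t_exp^â₂ · n^b₂ with â₂ = −a₂ and

ĉ₂ = H̄RI · c₂ · (Vi/Q̄)^a₂ / n̄^b₂.

Internally flows are in mL/s and times in s, so Vi/Q is a time; clinical
L/min is converted at the module boundary.

Per step (Δt = 0.0004 s by default): one new particle enters at l = 0 with
zero damage and participates in that step; every particle advances by
Δl = (Q·li/Vi)·Δt; every particle's damage is updated with the
effective-time rule — the exposure time that would produce its current HRI
at the end-of-step speed is computed, incremented by Δt, and the reduced
law re-evaluated. This keeps accumulation history-consistent: at constant
speed it collapses to total elapsed time regardless of the flow history,
and piecewise-constant histories compose exactly (tested against the
closed-form composition). Particles are removed on the step in which
l ≥ li; their final value is logged as the exit value. The cohort is a
strict FIFO, so the field is stored as flat arrays with an active window
and amortized compaction.

The pump-level HRI signal is the mean damage of all particles in the
region, times a correction factor f. The mean is biased low because
particle ages are uniformly distributed over one residence time T = Vi/Q:
averaging t^â₂ over [0, T] gives the exit value divided by (1 + â₂), so
f → 1 + â₂ = 1.394 as Δt → 0. f is calibrated by running the scheme at a
constant 0.5 L/min with f = 1 to steady state and taking direct/average;
the speed cancels exactly in the ratio (both carry n^b₂), which is also
tested. At Δt = 0.0004 s the calibration yields f ≈ 1.3936. Calibrating at
the lowest admissible flow uses the largest cohort (≈ 2112 particles), so
the discrete-age bias is smallest there; across the operating grid up to
12 L/min (cohorts down to ≈ 88) the corrected aggregate stays within 0.7%
of the direct law.

The scheme is not valid for backflow (Q ≤ 0): exposure time is undefined
and the trial data contain no such conditions. Simulations abort when
backflow is sustained (> 25 consecutive steps ≈ 10 ms); isolated
excursions hold the particle field for that step.

## Pump model

The closed-loop speed dynamics (controller included) are a unity-gain
second-order lag, 1/(k₂s² + k₁s + 1) with k₂ = 3.3e−6 s², k₁ = 0.0043 s,
plus a 2 ms dead time. The damping ratio is ≈ 1.18, so reference steps are
tracked without overshoot. The recurrence is the exact zero-order-hold
discretization (computed once per step size via a matrix exponential); the
dead time is a ring buffer of round(dead_time/Δt) reference samples.

The hydraulics follow L·dQ/dt = a·Q + b·n² + c·Qˣ·nʸ − ΔP with ΔP the head
pressure p_ao − p_lv, in clinical units (L/min, rpm, mmHg). The Sputnik1
set is a = −7.71 mmHg·min/L, b = 1.86e−6 mmHg/rpm², c = −5.49e−13
mmHg·min²/(L²·rpm³), L = 0.74 mmHg·s·min/L, (x, y) = (2, 3). Integration
is explicit Euler at the global step; the inertance is small (flow time
constant ≈ 0.1 s ≫ Δt) and the Euler solution agrees with a high-accuracy
reference to < 0.1% over constant-condition runs (tested).

`steady_flow` inverts the static curve for the x = 2 dialect (quadratic in
Q) and returns the root continuous with the linear (c → 0) solution — the
physical operating branch; the discarded root is far negative.

### Identification

(L, a, b, c) are identified per exponent pair (x, y) ∈ [−2, 4]² by linear
least squares on the rearranged ODE, with dQ/dt from finite differences
(4th-order central interior, one-sided ends). Columns are scaled to unit
norm before solving — the regressors span ~15 orders of magnitude and an
unscaled solve loses the small coefficients. Each candidate model is then
re-simulated (flow integrated against measured head pressure and speed)
and the pair with the smallest flow RMSE is selected; rank-deficient or
diverging candidates are skipped, and a dataset without speed and flow
variation raises an identifiability error.

The synthetic bench generator emits dwell segments joined by C³ smoothstep
flow ramps with the head pressure computed from the analytic dQ/dt, so the
finite-difference estimate is accurate through the junctions and noise-free
recovery is exact to ≳ 6 significant digits. A C¹ (cosine) ramp is not
enough: the curvature jump at the junctions leaves O(h) derivative errors
that bias the inertance estimate.

## Circulation model

The circulation is a lumped-parameter network of eight compliance
compartments — left/right ventricles and atria, systemic arteries and
veins, pulmonary arteries and veins — joined by resistances and the four
heart valves (ideal diodes with small series resistance, no regurgitation).
State variables are the eight volumes, so total blood volume is conserved
exactly by construction. The pump draws from the left ventricle and
returns to the systemic arterial compartment.

Both ventricles follow a time-varying elastance with a normalized
double-Hill activation shape (systole ≈ 36% of the cycle, scaling with
heart rate); the ventricles interact through a small linear septal
pressure-coupling term (coefficient 0.04) — the mechanism is named in the
source topology but no equations are printed, so a linear coupling is the
declared choice. Three patient knobs are exposed: `cflv` multiplies the
left-ventricular end-systolic elastance (1 = healthy, baseline 0.25),
`fRsys` scales systemic resistance, and `HR` sets the rate.

Below an unstressed-volume margin the heart chambers stiffen steeply
(2.5 mmHg/mL below V₀ + 10 mL): a purely linear diastolic compliance
cannot express the negative pressures of pump-induced suction and the
ventricle would be drained to negative volume at high speed; the
stiffening throttles pump inflow through the head pressure instead, which
is the physical suction mechanism.

The compartment values are this package's own heart-failure-tuned
parameterization; the source model's numbers are unpublished, so absolute
waveform levels are not reproducible and all circulation-level acceptance
is trend-based (monotone HRI and pulse-pressure responses to speed,
afterload and heart-rate changes). The unsupported cflv = 1 configuration
produces textbook hemodynamics (pulse pressure > 20 mmHg, stroke volume
40–120 mL, mean arterial pressure 60–120 mmHg; tested), and the cflv = 0.25
baseline reproduces a failing ventricle (less than 60% of the healthy
aortic-valve output).

Integration is explicit Euler at the same global Δt as the hemolysis model
(single-rate coupling). The fastest time constants (valve resistance times
ventricular elastance) are ≈ 4 ms ≫ Δt = 0.4 ms.

## Speed profiles and sweeps

Modulation profiles are rectangular waves synchronized with the cardiac
cycle, defined by mean speed, amplitude (n_high − n_low), duty
(T_high/T_cycle), phase shift, and a first-order Butterworth low-pass
cutoff. The rectangle anchors the exact mean: n_high = mean + (1−duty)·amp,
n_low = mean − duty·amp; whether the printed profiles are symmetric about
the mean for duty ≠ 50% is unstated, so mean-exactness is declared — it
makes mean-speed sweeps comparable. Filtering is causal (physically
realizable; the phase-shift sweep absorbs the lag) and run over 12 repeated
cycles so the kept cycle is in periodic steady state; feasibility
(6000 ≤ n_low, n_high ≤ 9000 rpm) is checked on the unfiltered wave.

The sweep enumerates means {6500, 7500, 8500} rpm, amplitudes 500–3000 rpm
(step 500), cutoffs {20, 5, 2} Hz and 5% duty/phase grids, keeping feasible
specs. The acceptance tests run the same sweep on a 3×3 duty/phase grid
({0.25, 0.5, 0.75} × {0, ⅓, ⅔}) to bound runtime; this is a problem-size
choice, the grids remain configurable.

Coupled runs use 15 cardiac cycles: transient cycles (the larger of one
impeller washout and 10 cycles) are discarded and the next 5 are analyzed.
Per-cycle metrics are the time-mean HRI, pulse pressure (max − min aortic
pressure), mean pump flow, and cardiac output defined as aortic-valve flow
plus pump flow (its definition under support is not standardized; total
systemic forward flow is the declared choice). The simulation is fully
deterministic — seeds only affect synthetic-data generators.

With this parameterization the modulation sweep reproduces the qualitative
findings: nearly all profiles raise cycle-mean HRI above the equal-mean
constant-speed reference (speed enters the damage law with exponent 5.45,
so any zero-mean speed ripple raises the mean by convexity, and flow
ripple adds through 1/Q^0.394), worst-case increases are tens of percent,
and at the lowest mean speed the best profile sits essentially at the
constant-speed level.

## Synthetic trial data

The trial generator emulates the structure of the 3-device ×
20-operating-point campaign: 18 points over six speeds within a
speed-dependent flow band plus two low-flow anchors at 1 L/min (6000 and
7000 rpm), device factors {1.5, 1.0, 0.95} (device 1 systematically
elevated), and multiplicative lognormal HRI noise (σ = 0.2). The flow band
interpolates linearly between 0.5–4 L/min at 6000 rpm and 3–8 L/min at
9000 rpm — a documented fixture convention approximating the physiological
envelope, not a measured quantity. Hourly blood-sample series (450 mL
loop, 35% HCT, Hb 12 g/dL, 6 h) are constructed by inverting the HRI
definition, with optional additive pfHb assay noise. Every generator is a
pure function of spec and seed.

What the generators do **not** emulate: assay-specific biases, blood aging
over a trial, temperature effects, inter-trial blood-batch variation, or
any dynamic (time-varying-condition) hemolysis response — the trials are
constant-condition by design, so passing recovery tests shows the fitting
pipeline is correct, not that the power law extrapolates beyond the tested
envelope or to transient conditions.

## Known limitations

* Absolute circulation waveforms (and therefore absolute coupled HRI
  percentages in the sweeps) depend on the package's own cardiovascular
  parameterization; only signs, orderings and magnitudes-of-trend are
  meaningful at that level.
* The hemolysis model is identified from constant-condition trials; its
  dynamic (Lagrangian) behavior is an extrapolation that has not been
  validated against time-varying in vitro data.
* Backflow and flows below 0.5 L/min are outside the model's domain.
* The correction factor is Δt-dependent (discrete-age bias ~â₂/2K per
  cohort of K particles); it must be recalibrated when the step or the
  geometry changes.
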