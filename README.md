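# lvadhemo

Trial-based, CFD-free hemolysis prediction for continuous-flow left
ventricular assist devices (LVADs).

Continuous-flow LVADs damage red blood cells through shear; elevated
hemolysis is associated with pump thrombosis, stroke and reduced survival.
Predicting how an operating mode — constant speed, or cardiac-cycle-
synchronized speed modulation — affects hemolysis usually requires CFD.
`lvadhemo` instead builds a pump-specific hemolysis model directly from in
vitro hemolysis trials and couples it to pump mechanics and a
lumped-parameter cardiovascular model, so that whole operating-mode sweeps
run in minutes on a laptop. It is aimed at researchers in mechanical
circulatory support and medical-device hemocompatibility.

## The model

The hemolysis rate index measured in a trial interval is

    HRI [%·mL/h] = (ΔpfHb / Hb) · 100 · (V/ΔT) · (100 − HCT)/100

and its dependence on the pump operating point is a modified power law

    HRI / H̄RI = c₂ · (Q/Q̄)^a₂ · (n/n̄)^b₂

with c₂ = 0.740, a₂ = −0.394, b₂ = 5.45 and scalings
(H̄RI, Q̄, n̄) = (43.22 %·mL/h, 4.65 L/min, 7415 rpm) for the Sputnik1
axial pump (defaults throughout). Robust (bisquare) nonlinear least
squares fits these parameters from per-device standardized trial data.

For time-varying conditions the law is rewritten in exposure time
(t_exp = Vi/Q over the impeller region, Vi = 7.04 mL, li = 55 mm) and
accumulated in discrete particles advected through the region; a
correction factor f ≈ 1.393 (analytically 1 + â₂ = 1.394 as Δt → 0) maps
the region-averaged particle damage onto the direct power law. The pump
itself is a second-order speed loop with dead time plus the pressure–flow
ODE L·dQ/dt = a·Q + b·n² + c·Qˣ·nʸ − ΔP, identified from bench data by
least squares with exponent selection by flow RMSE. An eight-compartment
cardiovascular model with time-varying ventricular elastances supplies the
head pressure ΔP = p_ao − p_lv. See `docs/methods.md` for details.

## Worked example

```python
import numpy as np
from lvadhemo import (
    PowerLawParams, static_hri, calibrate_f, steady_lagrangian_hri,
    run_simulation, summary_metrics,
)

plp = PowerLawParams()                     # Sputnik1 fit
print(static_hri(3.0, 7000.0, plp))        # 27.77  %·mL/h at 3 L/min, 7000 rpm

f = calibrate_f()                          # Lagrangian correction factor
print(f)                                   # 1.3936

print(steady_lagrangian_hri(3.0, 7000.0, correction=f))
                                           # 27.78  (0.04% from the direct law)

trace = run_simulation(7000.0, correction=f)   # coupled pump + circulation
print(summary_metrics(trace))
# {'mean_hri': 25.73, 'pulse_pressure': 3.64, 'cardiac_output': 3.79,
#  'mean_lvad_flow': 3.79, 'min_lvad_flow': 2.99, 'max_lvad_flow': 6.67}
```

The coupled cycle-mean HRI (25.7 %·mL/h) slightly exceeds the static value
at the cycle-mean flow (25.3 at 3.79 L/min): hemolysis rises steeply where
flow is lowest within the cycle, so pulsatile flow adds damage by
convexity, and the trace shows HRI fluctuating in counter-phase with pump
flow. Speed-modulation studies run through
`lvadhemo.modulation_sweep` / `lvadhemo.summarize_modulation`, which report
per mean speed the constant-speed reference, the best/worst-hemolysis
profiles and the highest-pulse-pressure profile with relative changes.

A CLI mirrors the library:

```
lvadhemo simulate --speed 7000 --out trace.csv
lvadhemo sweep-constant --out table.csv
lvadhemo sweep-modulation --out mod.csv
lvadhemo calibrate-f
lvadhemo fit-trials trials.csv --out fitted.yaml
lvadhemo flow-range
lvadhemo make-fixtures --kind trials --seed 1 --out fixtures/
```

All parameters (pump, power law, geometry, circulation, sweep grids) live
in one YAML config; omitted keys fall back to the Sputnik1 /
heart-failure-baseline defaults.

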