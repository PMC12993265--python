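"""Coupled pump / circulation / hemolysis simulation and operating-mode sweeps.

Per time step (single global rate, default dt = 0.0004 s):

1. mechanical speed step  (reference speed -> actual speed),
2. hydraulic flow step    (head pressure = p_ao - p_lv of the circulation),
3. circulation step       (pump flow moves volume from LV to aorta),
4. Lagrangian particle step and region-average HRI.

Traces are flagged transient until the first injected particle has washed
out of the impeller region and at least ten cardiac cycles have elapsed;
per-cycle metrics are computed on the following analysis cycles (default 5)
and averaged.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from . import cvs as cvsmod
from .cvs import CVSParams, cvs_init, cvs_step, elastance_activation
from .errors import BackflowError, InsufficientDataError
from .hemolysis import (
    ImpellerGeometry,
    ParticleField,
    PowerLawParams,
    advance_particles,
    aggregate_hri,
    calibrate_f,
    reduce_params,
)
from .profiles import ModulationSpec, enumerate_sweep, generate_profile
from .pump import HydraulicParams, MechParams, hydraulic_step, mech_init, mech_step, steady_flow

__all__ = [
    "SimulationTrace",
    "CycleMetrics",
    "run_simulation",
    "cycle_metrics",
    "summary_metrics",
    "constant_speed_sweep",
    "modulation_sweep",
    "summarize_modulation",
    "physiological_flow_range",
    "calibrated_correction",
]


@dataclass
class SimulationTrace:
    """Uniformly sampled coupled-simulation output."""

    t: np.ndarray  # s
    n_ref: np.ndarray  # rpm
    n: np.ndarray  # rpm
    Q: np.ndarray  # L/min
    dP: np.ndarray  # mmHg
    pao: np.ndarray  # mmHg
    plv: np.ndarray  # mmHg
    hri: np.ndarray  # %*mL/h
    q_av: np.ndarray  # aortic valve flow, mL/s
    dt: float
    steps_per_cycle: int
    n_transient_cycles: int

    @property
    def n_cycles(self) -> int:
        return len(self.t) // self.steps_per_cycle

    def cycle_slice(self, k: int) -> slice:
        return slice(k * self.steps_per_cycle, (k + 1) * self.steps_per_cycle)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "t_s": self.t,
                "n_ref_rpm": self.n_ref,
                "n_rpm": self.n,
                "Q_lpm": self.Q,
                "dP_mmHg": self.dP,
                "pao_mmHg": self.pao,
                "plv_mmHg": self.plv,
                "HRI": self.hri,
            }
        )

    def write_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


@dataclass(frozen=True)
class CycleMetrics:
    """Per-cycle summary of hemolysis, pulsatility and perfusion."""

    cycle: int
    mean_hri: float  # %*mL/h
    pulse_pressure: float  # mmHg
    cardiac_output: float  # L/min (aortic valve + pump)
    mean_lvad_flow: float  # L/min


_F_CACHE: dict[tuple, float] = {}


def calibrated_correction(
    plp: PowerLawParams = PowerLawParams(),
    geom: ImpellerGeometry = ImpellerGeometry(),
    dt: float = 0.0004,
) -> float:
    """Correction factor f for the given parameters, cached per session."""
    key = (plp, geom, dt)
    if key not in _F_CACHE:
        _F_CACHE[key] = calibrate_f(g=geom, dt=dt, p=plp)
    return _F_CACHE[key]


def run_simulation(
    profile: np.ndarray | float,
    cvs_params: CVSParams = CVSParams(),
    mech: MechParams = MechParams(),
    hyd: HydraulicParams = HydraulicParams(),
    plp: PowerLawParams = PowerLawParams(),
    geom: ImpellerGeometry = ImpellerGeometry(),
    dt: float = 0.0004,
    n_cycles: int = 15,
    correction: float | None = None,
    prescribed_flow: float | None = None,
    max_backflow_steps: int = 25,
) -> SimulationTrace:
    """Run the coupled model for ``n_cycles`` cardiac cycles.

    ``profile`` is either a constant reference speed (rpm) or one periodic
    cycle of reference speed sampled at ``dt`` (as produced by
    :func:`lvadhemo.profiles.generate_profile`).  ``prescribed_flow``
    bypasses the hydraulic and circulation models and drives the hemolysis
    model with a constant flow (test mode).  The simulation is fully
    deterministic; it aborts with :class:`BackflowError` if pump flow stays
    non-positive for more than ``max_backflow_steps`` consecutive steps and
    treats shorter excursions by holding the particle field.
    """
    steps_per_cycle = int(round(cvs_params.T_cycle / dt))
    if np.isscalar(profile):
        n_ref_cycle = np.full(steps_per_cycle, float(profile))
    else:
        n_ref_cycle = np.asarray(profile, float)
        if len(n_ref_cycle) != steps_per_cycle:
            raise ValueError(
                f"profile length {len(n_ref_cycle)} does not match the cardiac "
                f"cycle ({steps_per_cycle} samples at dt={dt})"
            )
    n_steps = n_cycles * steps_per_cycle
    if correction is None:
        correction = calibrated_correction(plp, geom, dt)
    rp = reduce_params(plp, geom)
    field = ParticleField(geometry=geom, correction=correction)

    # state initialization: speed matched to the profile start, flow on the
    # static pump curve against the initial head pressure
    cvs_state = cvs_init(cvs_params)
    pao, plv = float(cvs_state.p[4]), float(cvs_state.p[0])
    pump_state = mech_init(n_ref_cycle[0], dt, mech)
    if prescribed_flow is None:
        pump_state.Q = max(0.5, steady_flow(n_ref_cycle[0], pao - plv, hyd))
    else:
        pump_state.Q = prescribed_flow

    tr = {k: np.empty(n_steps) for k in
          ("n_ref", "n", "Q", "dP", "pao", "plv", "hri", "q_av")}
    act_cycle = elastance_activation(
        (np.arange(1, steps_per_cycle + 1) % steps_per_cycle) / steps_per_cycle,
        cvs_params.systole_fraction,
    )
    first_exit_step = None
    backflow_run = 0
    for i in range(n_steps):
        j = i % steps_per_cycle
        n_ref = n_ref_cycle[j]
        pump_state = mech_step(pump_state, n_ref, dt, mech)
        dP = pao - plv
        if prescribed_flow is None:
            pump_state = hydraulic_step(pump_state, pump_state.n, dP, dt, hyd)
            cvs_state, pao, plv = cvs_step(cvs_state, max(0.0, pump_state.Q),
                                           dt, cvs_params, act_new=act_cycle[j])
        Q = pump_state.Q
        if Q > 0:
            advance_particles(field, Q, pump_state.n, dt, rp)
            backflow_run = 0
        else:
            backflow_run += 1
            if backflow_run > max_backflow_steps:
                raise BackflowError(
                    f"sustained pump backflow at step {i} (t={i * dt:.3f} s); "
                    "the hemolysis model is not valid for backflow"
                )
        if first_exit_step is None and field.total_exited > 0:
            first_exit_step = i
        tr["n_ref"][i] = n_ref
        tr["n"][i] = pump_state.n
        tr["Q"][i] = Q
        tr["dP"][i] = dP
        tr["pao"][i] = pao
        tr["plv"][i] = plv
        tr["hri"][i] = aggregate_hri(field) if field.count else 0.0
        tr["q_av"][i] = cvs_state.q_av if prescribed_flow is None else 0.0
        if not (math.isfinite(Q) and math.isfinite(pao)):
            raise FloatingPointError(f"non-finite state at step {i}")

    washout_cycles = (
        n_cycles if first_exit_step is None
        else math.ceil((first_exit_step + 1) / steps_per_cycle)
    )
    n_transient = max(10, washout_cycles)
    return SimulationTrace(
        t=np.arange(n_steps) * dt,
        n_ref=tr["n_ref"], n=tr["n"], Q=tr["Q"], dP=tr["dP"],
        pao=tr["pao"], plv=tr["plv"], hri=tr["hri"], q_av=tr["q_av"],
        dt=dt, steps_per_cycle=steps_per_cycle, n_transient_cycles=n_transient,
    )


def cycle_metrics(trace: SimulationTrace) -> list[CycleMetrics]:
    """Per-cycle metrics for every complete post-transient cycle."""
    out = []
    for k in range(trace.n_transient_cycles, trace.n_cycles):
        s = trace.cycle_slice(k)
        pao = trace.pao[s]
        out.append(
            CycleMetrics(
                cycle=k,
                mean_hri=float(np.mean(trace.hri[s])),
                pulse_pressure=float(np.max(pao) - np.min(pao)),
                cardiac_output=float(
                    np.mean(trace.q_av[s]) * cvsmod.MLPS_TO_LPM
                    + np.mean(trace.Q[s])
                ),
                mean_lvad_flow=float(np.mean(trace.Q[s])),
            )
        )
    if not out:
        raise InsufficientDataError("no complete post-transient cycle in trace")
    return out


def summary_metrics(trace: SimulationTrace) -> dict[str, float]:
    """Analysis-cycle averages of the per-cycle metrics."""
    cm = cycle_metrics(trace)
    return {
        "mean_hri": float(np.mean([c.mean_hri for c in cm])),
        "pulse_pressure": float(np.mean([c.pulse_pressure for c in cm])),
        "cardiac_output": float(np.mean([c.cardiac_output for c in cm])),
        "mean_lvad_flow": float(np.mean([c.mean_lvad_flow for c in cm])),
        "min_lvad_flow": float(np.min(trace.Q[trace.n_transient_cycles
                                              * trace.steps_per_cycle:])),
        "max_lvad_flow": float(np.max(trace.Q[trace.n_transient_cycles
                                              * trace.steps_per_cycle:])),
    }


def constant_speed_sweep(
    speeds=np.arange(6000.0, 9000.0 + 1, 100.0),
    variants: dict[str, CVSParams] | None = None,
    n_cycles: int = 15,
    dt: float = 0.0004,
    **kwargs,
) -> pd.DataFrame:
    """Metrics table over constant speeds for each cardiovascular variant.

    The default variants are the baseline (HR 75, fRsys 1, cflv 0.25) and
    individual changes of cflv, fRsys and heart rate.  Simulation failures
    (e.g. backflow) are recorded per cell and the sweep continues.
    """
    if variants is None:
        base = CVSParams()
        variants = {
            "baseline": base,
            "cflv=0.1": replace(base, cflv=0.1),
            "cflv=0.4": replace(base, cflv=0.4),
            "fRsys=0.75": replace(base, fRsys=0.75),
            "fRsys=1.25": replace(base, fRsys=1.25),
            "HR=60": replace(base, HR=60.0),
            "HR=120": replace(base, HR=120.0),
        }
    rows = []
    for name, cp in variants.items():
        for speed in speeds:
            row = dict(variant=name, speed=float(speed))
            try:
                trace = run_simulation(float(speed), cp, n_cycles=n_cycles,
                                       dt=dt, **kwargs)
                row.update(summary_metrics(trace))
            except (BackflowError, FloatingPointError) as exc:
                row["error"] = str(exc)
            rows.append(row)
    return pd.DataFrame(rows)


def modulation_sweep(
    specs: list[ModulationSpec] | None = None,
    cvs_params: CVSParams = CVSParams(),
    n_cycles: int = 15,
    dt: float = 0.0004,
    **kwargs,
) -> pd.DataFrame:
    """Metrics for each modulation spec plus constant-speed references.

    Returns a tidy table with one row per spec (kind="modulated") and one
    row per distinct mean speed (kind="constant").
    """
    if specs is None:
        specs = enumerate_sweep()
    rows = []
    for mean in sorted({s.mean_speed for s in specs}):
        trace = run_simulation(mean, cvs_params, n_cycles=n_cycles, dt=dt, **kwargs)
        rows.append(dict(kind="constant", mean_speed=mean, amplitude=0.0,
                         duty=np.nan, phase_shift=np.nan, cutoff=np.nan,
                         **summary_metrics(trace)))
    for spec in specs:
        row = dict(kind="modulated", mean_speed=spec.mean_speed,
                   amplitude=spec.amplitude, duty=spec.duty,
                   phase_shift=spec.phase_shift, cutoff=spec.cutoff)
        try:
            prof = generate_profile(spec, cvs_params.T_cycle, dt)
            trace = run_simulation(prof, cvs_params, n_cycles=n_cycles, dt=dt,
                                   **kwargs)
            row.update(summary_metrics(trace))
        except (BackflowError, FloatingPointError) as exc:
            row["error"] = str(exc)
        rows.append(row)
    return pd.DataFrame(rows)


def summarize_modulation(table: pd.DataFrame) -> pd.DataFrame:
    """Best/worst profiles per mean speed with changes vs. constant speed."""
    out = []
    ok = table[table["error"].isna()] if "error" in table.columns else table
    for mean, grp in ok.groupby("mean_speed"):
        const = grp[grp.kind == "constant"]
        mod = grp[grp.kind == "modulated"]
        if const.empty or mod.empty:
            continue
        ref_hri = float(const.mean_hri.iloc[0])
        ref_pp = float(const.pulse_pressure.iloc[0])
        lo = mod.loc[mod.mean_hri.idxmin()]
        hi = mod.loc[mod.mean_hri.idxmax()]
        pp = mod.loc[mod.pulse_pressure.idxmax()]
        out.append(
            dict(
                mean_speed=mean,
                constant_hri=ref_hri,
                constant_pp=ref_pp,
                frac_profiles_increasing_hri=float(np.mean(mod.mean_hri > ref_hri)),
                min_hri=float(lo.mean_hri),
                min_hri_change_pct=100.0 * (lo.mean_hri / ref_hri - 1.0),
                max_hri=float(hi.mean_hri),
                max_hri_change_pct=100.0 * (hi.mean_hri / ref_hri - 1.0),
                max_pp=float(pp.pulse_pressure),
                max_pp_change_pct=100.0 * (pp.pulse_pressure / ref_pp - 1.0),
                max_pp_profile_hri_change_pct=100.0 * (pp.mean_hri / ref_hri - 1.0),
            )
        )
    return pd.DataFrame(out)


def physiological_flow_range(
    speeds=(6000.0, 7000.0, 8000.0, 9000.0),
    cflv_values=(0.1, 0.25, 0.4),
    hr_values=(60.0, 90.0, 120.0),
    frsys_values=(0.75, 1.0, 1.25),
    floor: float = 0.5,
    n_cycles: int = 15,
    dt: float = 0.0004,
    **kwargs,
) -> pd.DataFrame:
    """Per-speed pump-flow envelope across cardiovascular parameter combinations.

    For each speed all cflv x HR x fRsys combinations are simulated to a
    periodic steady state and the post-transient cycle minimum and maximum
    pump flows are recorded; the lower bound is floored at ``floor`` L/min
    (below which in vitro blood mixing is unreliable).  Combinations that
    abort with backflow are excluded and counted.
    """
    rows = []
    for speed in speeds:
        qmin, qmax = np.inf, -np.inf
        excluded = 0
        for cflv in cflv_values:
            for hr in hr_values:
                for fr in frsys_values:
                    cp = CVSParams(HR=hr, cflv=cflv, fRsys=fr)
                    try:
                        trace = run_simulation(float(speed), cp,
                                               n_cycles=n_cycles, dt=dt, **kwargs)
                        sm = summary_metrics(trace)
                    except (BackflowError, FloatingPointError):
                        excluded += 1
                        continue
                    qmin = min(qmin, sm["min_lvad_flow"])
                    qmax = max(qmax, sm["max_lvad_flow"])
        rows.append(
            dict(speed=float(speed), Q_min=max(floor, qmin), Q_max=qmax,
                 n_excluded=excluded)
        )
    return pd.DataFrame(rows)
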