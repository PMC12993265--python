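"""Lumped-parameter model of the LVAD-supported cardiovascular system.

Eight compliance compartments — left ventricle (lv), right ventricle (rv),
left atrium (la), right atrium (ra), systemic arteries (sa), systemic veins
(sv), pulmonary arteries (pa) and pulmonary veins (pv) — are connected by
resistances and ideal diodes (the four heart valves, each with a small
series resistance).  Both ventricles follow a time-varying elastance with a
double-Hill activation shape; the ventricles interact through a linear
septal pressure-coupling term.  The pump draws flow from the left ventricle
and returns it to the systemic arterial compartment, so head pressure seen
by the pump is p_ao - p_lv.

Three parameters are exposed as the primary patient knobs:

* ``cflv``   — scales the left-ventricular end-systolic elastance; 1 is a
  healthy ventricle, the heart-failure baseline uses 0.25.
* ``fRsys``  — multiplies the systemic vascular resistance (afterload).
* ``HR``     — heart rate in bpm; systole occupies a fixed fraction of the
  cycle.

The numeric compartment values are this package's own heart-failure-tuned
parameterization; they aim at textbook hemodynamics (unsupported baseline:
low cardiac output, preserved filling pressures), not at any specific
published parameter set.  Units: mmHg, mL, s.

State variables are the eight compartment volumes, so total blood volume is
conserved exactly by construction (every flow leaves one compartment and
enters another; pump flow moves volume from lv to sa).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

__all__ = ["CVSParams", "CVSState", "cvs_init", "cvs_step", "elastance_activation"]

MLPS_TO_LPM = 60.0 / 1000.0


@dataclass(frozen=True)
class CVSParams:
    """Compartment and coupling parameters (heart-failure baseline defaults)."""

    # patient knobs
    HR: float = 75.0  # bpm
    cflv: float = 0.25  # LV contractility factor (1 = healthy)
    fRsys: float = 1.0  # systemic resistance scale

    # ventricular elastances, mmHg/mL (end-systolic values are for cflv = 1)
    E_lv_max: float = 3.0
    E_lv_min: float = 0.09
    E_rv_max: float = 0.65
    E_rv_min: float = 0.045
    V0_lv: float = 15.0  # unstressed volumes, mL
    V0_rv: float = 15.0

    # passive compartment compliances, mL/mmHg, and unstressed volumes, mL
    C_la: float = 12.0
    C_ra: float = 16.0
    C_sa: float = 1.6
    C_sv: float = 65.0
    C_pa: float = 4.5
    C_pv: float = 14.0
    V0_la: float = 20.0
    V0_ra: float = 20.0
    V0_sa: float = 600.0
    V0_sv: float = 2700.0
    V0_pa: float = 120.0
    V0_pv: float = 350.0

    # resistances, mmHg*s/mL
    R_sys: float = 1.05  # systemic arteries -> veins (scaled by fRsys)
    R_vr: float = 0.045  # systemic veins -> right atrium
    R_pul: float = 0.085  # pulmonary arteries -> veins
    R_pvr: float = 0.025  # pulmonary veins -> left atrium
    R_mv: float = 0.006  # mitral valve
    R_av: float = 0.010  # aortic valve
    R_tv: float = 0.006  # tricuspid valve
    R_pv: float = 0.008  # pulmonary valve

    # septal pressure coupling between the ventricular free walls
    k_septum: float = 0.04

    # suction stiffening: below V0 + V_suction_margin a heart chamber's
    # pressure falls steeply (K_suction, mmHg/mL), throttling pump inflow
    # instead of letting the chamber collapse to negative volume
    K_suction: float = 2.5
    V_suction_margin: float = 10.0

    # systolic fraction of the cycle used by the activation shape
    systole_fraction: float = 0.36

    def __post_init__(self) -> None:
        if not 0 < self.cflv <= 1:
            raise ValueError("cflv must be in (0, 1]")
        if self.fRsys <= 0 or self.HR <= 0:
            raise ValueError("fRsys and HR must be positive")
        for name in ("C_la", "C_ra", "C_sa", "C_sv", "C_pa", "C_pv",
                     "R_sys", "R_vr", "R_pul", "R_pvr",
                     "R_mv", "R_av", "R_tv", "R_pv",
                     "E_lv_max", "E_lv_min", "E_rv_max", "E_rv_min"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @property
    def T_cycle(self) -> float:
        return 60.0 / self.HR


@dataclass
class CVSState:
    """Compartment volumes (mL) and cycle phase in [0, 1)."""

    V: np.ndarray  # [lv, rv, la, ra, sa, sv, pa, pv]
    phase: float = 0.0
    # diagnostics of the last step
    p: np.ndarray | None = None  # compartment pressures, same order
    q_av: float = 0.0  # aortic-valve flow, mL/s

    def copy(self) -> "CVSState":
        out = CVSState(V=self.V.copy(), phase=self.phase, q_av=self.q_av)
        out.p = None if self.p is None else self.p.copy()
        return out

    @property
    def total_volume(self) -> float:
        return float(np.sum(self.V))


IDX = {k: i for i, k in enumerate(("lv", "rv", "la", "ra", "sa", "sv", "pa", "pv"))}


def elastance_activation(phase: np.ndarray | float, systole_fraction: float = 0.36):
    """Normalized double-Hill activation e(phase) in [0, 1].

    ``phase`` is the fraction of the cardiac cycle elapsed since the onset of
    ventricular contraction.  The shape is the product of an ascending and a
    descending Hill function of the normalized time, rescaled to peak at 1;
    systole occupies roughly ``systole_fraction`` of the cycle.
    """
    tau = np.asarray(phase, dtype=float) / (1.25 * systole_fraction)
    h1 = (tau / 0.303) ** 1.32
    h2 = (tau / 0.508) ** 21.9
    e = (h1 / (1 + h1)) / (1 + h2)
    return e / 0.5980220246503491  # peak of the unnormalized shape


def _suction(V: float, V0: float, p: CVSParams) -> float:
    d = V - (V0 + p.V_suction_margin)
    return p.K_suction * d if d < 0 else 0.0


def _pressures(V: np.ndarray, act: float, p: CVSParams) -> np.ndarray:
    E_lv = p.E_lv_min + act * (p.cflv * p.E_lv_max - p.E_lv_min)
    E_rv = p.E_rv_min + act * (p.E_rv_max - p.E_rv_min)
    p_lv_free = E_lv * (V[0] - p.V0_lv) + _suction(V[0], p.V0_lv, p)
    p_rv_free = E_rv * (V[1] - p.V0_rv) + _suction(V[1], p.V0_rv, p)
    pr = np.empty(8)
    pr[0] = p_lv_free + p.k_septum * p_rv_free
    pr[1] = p_rv_free + p.k_septum * p_lv_free
    pr[2] = (V[2] - p.V0_la) / p.C_la + _suction(V[2], p.V0_la, p)
    pr[3] = (V[3] - p.V0_ra) / p.C_ra + _suction(V[3], p.V0_ra, p)
    pr[4] = (V[4] - p.V0_sa) / p.C_sa
    pr[5] = (V[5] - p.V0_sv) / p.C_sv
    pr[6] = (V[6] - p.V0_pa) / p.C_pa
    pr[7] = (V[7] - p.V0_pv) / p.C_pv
    return pr


def cvs_init(p: CVSParams = CVSParams()) -> CVSState:
    """State at end-diastole with documented baseline volumes."""
    V = np.array([160.0, 130.0, 90.0, 75.0, 700.0, 2990.0, 175.0, 520.0])
    state = CVSState(V=V, phase=0.0)
    state.p = _pressures(V, float(elastance_activation(0.0, p.systole_fraction)), p)
    return state


def cvs_step(
    state: CVSState,
    Q_lvad: float,
    dt: float,
    p: CVSParams = CVSParams(),
    act_new: float | None = None,
) -> tuple[CVSState, float, float]:
    """Advance the circulation one explicit-Euler step.

    ``Q_lvad`` is the pump flow in L/min, drawn from the left ventricle and
    returned to the systemic arterial compartment.  Returns
    ``(new_state, p_ao, p_lv)`` where the pressures are evaluated at the new
    state (these feed the pump head pressure of the next step).
    ``act_new`` optionally supplies the precomputed activation value at the
    new phase (a lookup-table optimization used by the simulation loop).
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    V = state.V
    if state.p is not None:
        pr = state.p  # pressures at the current (volume, phase), cached
    else:
        act = float(elastance_activation(state.phase, p.systole_fraction))
        pr = _pressures(V, act, p)
    p_lv, p_rv, p_la, p_ra, p_sa, p_sv, p_pa, p_pv = pr

    q_mv = max(0.0, (p_la - p_lv) / p.R_mv)
    q_av = max(0.0, (p_lv - p_sa) / p.R_av)
    q_tv = max(0.0, (p_ra - p_rv) / p.R_tv)
    q_pv = max(0.0, (p_rv - p_pa) / p.R_pv)
    q_sys = (p_sa - p_sv) / (p.R_sys * p.fRsys)
    q_vr = (p_sv - p_ra) / p.R_vr
    q_pul = (p_pa - p_pv) / p.R_pul
    q_pvr = (p_pv - p_la) / p.R_pvr
    q_pump = Q_lvad / MLPS_TO_LPM  # L/min -> mL/s

    Vn = np.array(
        [
            V[0] + dt * (q_mv - q_av - q_pump),
            V[1] + dt * (q_tv - q_pv),
            V[2] + dt * (q_pvr - q_mv),
            V[3] + dt * (q_vr - q_tv),
            V[4] + dt * (q_av + q_pump - q_sys),
            V[5] + dt * (q_sys - q_vr),
            V[6] + dt * (q_pv - q_pul),
            V[7] + dt * (q_pul - q_pvr),
        ]
    )
    if Vn.min() < 0:
        bad = [k for k, i in IDX.items() if Vn[i] < 0]
        raise FloatingPointError(
            f"negative compartment volume in {bad}; reduce dt or check parameters"
        )
    out = CVSState(V=Vn, q_av=q_av)
    out.phase = (state.phase + dt / p.T_cycle) % 1.0
    if act_new is None:
        act_new = float(elastance_activation(out.phase, p.systole_fraction))
    out.p = _pressures(out.V, act_new, p)
    return out, float(out.p[4]), float(out.p[0])
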