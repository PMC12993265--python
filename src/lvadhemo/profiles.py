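"""Cardiac-cycle-synchronized pump speed profiles.

A modulation profile is a rectangular speed wave, synchronized with the
cardiac cycle, smoothed by a causal first-order Butterworth low-pass and
optionally phase-shifted within the cycle.  The rectangle is built so that
its time-average equals the requested mean speed exactly:

    n_high = mean + (1 - duty) * amplitude
    n_low  = mean - duty * amplitude

with ``duty = T_high / T_cycle``.  A 20 Hz cutoff leaves the wave nearly
rectangular; 2 Hz renders it almost sinusoidal.  Feasibility is checked on
the unfiltered wave against the clinical speed window (6000-9000 rpm for
the Sputnik1); the filtered extremes lie strictly inside it.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product

import numpy as np
from scipy.signal import butter, lfilter

from .errors import FeasibilityError

__all__ = [
    "ModulationSpec",
    "generate_profile",
    "enumerate_sweep",
    "SPEED_MIN",
    "SPEED_MAX",
]

SPEED_MIN = 6000.0  # rpm, clinical window lower bound
SPEED_MAX = 9000.0


@dataclass(frozen=True)
class ModulationSpec:
    """One speed-modulation profile specification."""

    mean_speed: float  # rpm
    amplitude: float  # rpm, n_high - n_low
    duty: float = 0.5  # T_high / T_cycle, in (0, 1)
    phase_shift: float = 0.0  # fraction of T_cycle, in [0, 1)
    cutoff: float = 20.0  # Hz, first-order low-pass

    def __post_init__(self) -> None:
        if not 0 < self.duty < 1:
            raise ValueError("duty must be in (0, 1)")
        if not 0 <= self.phase_shift < 1:
            raise ValueError("phase_shift must be in [0, 1)")
        if self.amplitude < 0 or self.cutoff <= 0:
            raise ValueError("amplitude must be >= 0 and cutoff > 0")

    @property
    def n_high(self) -> float:
        return self.mean_speed + (1.0 - self.duty) * self.amplitude

    @property
    def n_low(self) -> float:
        return self.mean_speed - self.duty * self.amplitude

    def check_feasible(
        self, lo: float = SPEED_MIN, hi: float = SPEED_MAX
    ) -> "ModulationSpec":
        if self.n_high > hi:
            raise FeasibilityError(
                f"n_high = {self.n_high:.0f} rpm exceeds the {hi:.0f} rpm bound"
            )
        if self.n_low < lo:
            raise FeasibilityError(
                f"n_low = {self.n_low:.0f} rpm is below the {lo:.0f} rpm bound"
            )
        return self

    def is_feasible(self, lo: float = SPEED_MIN, hi: float = SPEED_MAX) -> bool:
        return self.n_low >= lo and self.n_high <= hi


def generate_profile(
    spec: ModulationSpec, T_cycle: float, dt: float, warmup_cycles: int = 12
) -> np.ndarray:
    """One periodic cycle of the filtered reference-speed profile (rpm).

    The rectangular wave (high segment first) is filtered causally over
    ``warmup_cycles`` repeated cycles so the filter reaches its periodic
    steady state, then the last cycle is kept and rotated by the phase
    shift.  The filter has unity DC gain, so the cycle average equals
    ``spec.mean_speed`` up to the rectangle's sampling granularity.
    """
    spec.check_feasible()
    n_samp = int(round(T_cycle / dt))
    if abs(n_samp * dt - T_cycle) > dt:
        raise ValueError("dt must divide T_cycle to within one sample")
    n_high_samp = int(round(spec.duty * n_samp))
    wave = np.full(n_samp, spec.n_low)
    wave[:n_high_samp] = spec.n_high
    if spec.amplitude == 0:
        return np.full(n_samp, spec.mean_speed)

    b, a = butter(1, spec.cutoff, btype="low", fs=1.0 / dt)
    filtered = lfilter(b, a, np.tile(wave, warmup_cycles))[-n_samp:]
    shift = int(round(spec.phase_shift * n_samp))
    return np.roll(filtered, shift)


def enumerate_sweep(
    mean_speeds=(6500.0, 7500.0, 8500.0),
    amplitudes=tuple(float(a) for a in range(500, 3001, 500)),
    cutoffs=(20.0, 5.0, 2.0),
    duty_step: float = 0.05,
    phase_step: float = 0.05,
    duties=None,
    phases=None,
    lo: float = SPEED_MIN,
    hi: float = SPEED_MAX,
) -> list[ModulationSpec]:
    """Cartesian modulation sweep, filtered to feasible specs.

    Defaults follow the study grid: means 6500/7500/8500 rpm, amplitudes
    500-3000 rpm in 500 rpm steps, cutoffs 20/5/2 Hz, duty and phase on 5%
    grids.  Pass explicit ``duties``/``phases`` for a coarser grid.
    """
    if duties is None:
        duties = np.round(np.arange(duty_step, 1.0 - duty_step / 2, duty_step), 10)
    if phases is None:
        phases = np.round(np.arange(0.0, 1.0 - phase_step / 2, phase_step), 10)
    out = []
    for m, amp, co, d, ph in product(mean_speeds, amplitudes, cutoffs, duties, phases):
        spec = ModulationSpec(
            mean_speed=m, amplitude=amp, duty=float(d), phase_shift=float(ph),
            cutoff=co,
        )
        if spec.is_feasible(lo, hi):
            out.append(spec)
    return out
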