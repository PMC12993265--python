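"""Seeded synthetic fixtures: hemolysis trials, blood-sample series, bench data.

Every generator is a pure function of its spec and seed.  The trial
generator emulates the structure of a 3-device, 20-operating-point in vitro
hemolysis campaign: 18 points spread evenly over the clinical speed range
within a speed-dependent physiological flow band, plus two low-flow points
at 1 L/min (6000 and 7000 rpm); one device is systematically elevated.
HRI magnitudes come from the static power law times a per-device factor and
multiplicative lognormal noise.  The flow band is a documented fixture
convention: it interpolates linearly between 0.5-4 L/min at 6000 rpm and
3-8 L/min at 9000 rpm.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import GeneratorError
from .hemolysis import PowerLawParams, static_hri
from .pump import BenchDataset, HydraulicParams, static_head
from .trials import BloodSample, TrialRecord

__all__ = [
    "TrialGeneratorSpec",
    "default_operating_grid",
    "generate_trials",
    "generate_samples",
    "generate_bench_data",
]

# trial-loop constants of the emulated campaign
LOOP_VOLUME_ML = 450.0
LOOP_HCT_PCT = 35.0
LOOP_HB_G_DL = 12.0
TRIAL_HOURS = 6

FLOW_BAND = {6000.0: (0.5, 4.0), 9000.0: (3.0, 8.0)}  # fixture convention


def _flow_band(speed: float) -> tuple[float, float]:
    (s0, (lo0, hi0)), (s1, (lo1, hi1)) = sorted(FLOW_BAND.items())
    w = np.clip((speed - s0) / (s1 - s0), 0.0, 1.0)
    return lo0 + w * (lo1 - lo0), hi0 + w * (hi1 - hi0)


def default_operating_grid() -> list[tuple[float, float]]:
    """20 (speed rpm, flow L/min) points: 6 speeds x 3 flows + two at 1 L/min."""
    grid = []
    for speed in np.linspace(6000.0, 9000.0, 6):
        lo, hi = _flow_band(float(speed))
        for q in np.linspace(lo, hi, 3):
            grid.append((float(speed), round(float(q), 2)))
    grid.append((6000.0, 1.0))
    grid.append((7000.0, 1.0))
    return grid


@dataclass(frozen=True)
class TrialGeneratorSpec:
    """Specification of a synthetic hemolysis-trial campaign."""

    grid: tuple = field(default_factory=lambda: tuple(default_operating_grid()))
    device_factors: tuple = (1.5, 1.0, 0.95)
    noise_sigma: float = 0.2  # lognormal sigma on HRI
    seed: int = 0
    full_samples: bool = True  # emit hourly blood samples, not just HRI
    assay_noise_mg_dl: float = 0.0  # additive pfHb noise inside samples

    def __post_init__(self) -> None:
        if any(q < 0.5 for _, q in self.grid):
            raise GeneratorError("all grid flows must be >= 0.5 L/min")
        if self.noise_sigma < 0 or self.assay_noise_mg_dl < 0:
            raise GeneratorError("noise levels must be non-negative")


def generate_samples(
    true_hri: float,
    V: float = LOOP_VOLUME_ML,
    HCT: float = LOOP_HCT_PCT,
    Hb: float = LOOP_HB_G_DL,
    hours: int = TRIAL_HOURS,
    seed: int | np.random.Generator = 0,
    pfHb0: float = 5.0,
    assay_noise_mg_dl: float = 0.0,
) -> list[BloodSample]:
    """Hourly blood samples whose interval HRI evaluates to ``true_hri``.

    Inverts the HRI definition: each 1-h interval needs
    dpfHb = true_hri * 10 * Hb / (V * (100 - HCT) / 100) mg/dL; optional
    additive Gaussian assay noise perturbs the pfHb readings.
    """
    if true_hri < 0:
        raise GeneratorError("true_hri must be non-negative")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    d_pfhb = true_hri * 10.0 * Hb / (V * (100.0 - HCT) / 100.0)
    pfhb = pfHb0 + d_pfhb * np.arange(hours + 1)
    if assay_noise_mg_dl > 0:
        pfhb = pfhb + rng.normal(0.0, assay_noise_mg_dl, size=hours + 1)
        pfhb = np.maximum(pfhb, 0.0)
    if pfhb[-1] >= Hb * 1000.0:
        raise GeneratorError(
            f"implied pfHb {pfhb[-1]:.0f} mg/dL exceeds total hemoglobin"
        )
    return [
        BloodSample(t=float(h), pfHb=float(pfhb[h]), Hb=Hb, HCT=HCT, V=V)
        for h in range(hours + 1)
    ]


def generate_trials(
    spec: TrialGeneratorSpec = TrialGeneratorSpec(),
    plp: PowerLawParams = PowerLawParams(),
) -> list[TrialRecord]:
    """Synthetic trial records for each device over the operating grid.

    True HRI per device and grid point is
    ``device_factor * static_hri(Q, n) * exp(noise_sigma * z)``; when
    ``full_samples`` is set each trial also carries an hourly blood-sample
    series consistent with its HRI, otherwise only the derived ``hri``.
    """
    rng = np.random.default_rng(spec.seed)
    out = []
    for d, factor in enumerate(spec.device_factors, start=1):
        for n, q in spec.grid:
            hri = factor * static_hri(q, n, plp)
            if spec.noise_sigma > 0:
                hri *= float(np.exp(rng.normal(0.0, spec.noise_sigma)))
            samples = (
                generate_samples(
                    hri, seed=rng, assay_noise_mg_dl=spec.assay_noise_mg_dl
                )
                if spec.full_samples
                else []
            )
            out.append(
                TrialRecord(device_id=f"LVAD{d}", n=n, Q=q, samples=samples, hri=hri)
            )
    return out


def generate_bench_data(
    params: HydraulicParams = HydraulicParams(),
    speeds=(6000.0, 6500.0, 7000.0, 7500.0, 8000.0, 8500.0, 9000.0),
    flows=(0.0, 1.0, 2.0, 3.0, 4.0, 5.0, 6.0),
    dwell_s: float = 1.0,
    ramp_s: float = 1.0,
    fs_hz: float = 200.0,
    noise_dp_mmhg: float = 0.0,
    seed: int = 0,
) -> BenchDataset:
    """Bench records with steady dwells and smooth flow ramps between points.

    The (speed, flow) grid is visited speed by speed; within a speed the
    flow follows cosine-smoothed ramps between dwells, and the head pressure
    is computed exactly from the pump ODE with the analytic dQ/dt of the
    trajectory.  Optional additive Gaussian noise perturbs dP only.
    """
    if len(speeds) < 3 or len(flows) < 3:
        raise GeneratorError("grid must span at least 3 speeds and 3 flows")
    dt = 1.0 / fs_hz
    n_dwell = int(round(dwell_s * fs_hz))
    n_ramp = int(round(ramp_s * fs_hz))
    Q_parts, dQ_parts, n_parts = [], [], []
    prev = None  # flow is kept continuous across speed changes
    for spd in speeds:
        for q in flows:
            if prev is not None:
                # C3 smoothstep ramp: finite-difference derivative estimates
                # stay accurate across the dwell/ramp junctions
                s = np.arange(1, n_ramp + 1) / n_ramp
                shape = ((-20.0 * s + 70.0) * s - 84.0) * s**5 + 35.0 * s**4
                Q_parts.append(prev + (q - prev) * shape)
                dQ_parts.append((q - prev) / ramp_s * 140.0 * s**3
                                * (1.0 - s) ** 3)
                n_parts.append(np.full(n_ramp, spd))
            Q_parts.append(np.full(n_dwell, q))
            dQ_parts.append(np.zeros(n_dwell))
            n_parts.append(np.full(n_dwell, spd))
            prev = q
    Q = np.concatenate(Q_parts)
    dQdt = np.concatenate(dQ_parts)
    n = np.concatenate(n_parts)
    with np.errstate(divide="ignore", invalid="ignore"):
        head = np.array([static_head(qi, ni, params) for qi, ni in zip(Q, n)])
    dP = head - params.L * dQdt
    if noise_dp_mmhg > 0:
        rng = np.random.default_rng(seed)
        dP = dP + rng.normal(0.0, noise_dp_mmhg, size=len(dP))
    t = np.arange(len(Q)) * dt
    return BenchDataset(t=t, n=n, Q=Q, dP=dP)
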