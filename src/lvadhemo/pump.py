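"""Mechanical and hydraulic models of an axial-flow blood pump.

The mechanical subsystem is the closed-loop speed dynamics from reference
speed ``n_ref`` to actual speed ``n``, modelled as a second-order lag (PT2)
with unity DC gain plus a transport dead time.  The hydraulic subsystem
relates speed ``n`` (rpm), pump flow ``Q`` (L/min) and head pressure
``dP = p_ao - p_lv`` (mmHg) through a first-order nonlinear ODE

    L * dQ/dt = a*Q + b*n**2 + c*Q**x * n**y - dP

whose coefficients ``(L, a, b, c)`` are identified from bench data by linear
least squares while the integer exponents ``(x, y)`` are selected over a grid
by the flow RMSE of the re-simulated model.

Clinical units are used throughout this module: rpm, L/min, mmHg, seconds.
Default parameter values are the identified Sputnik1 set.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd
from scipy.linalg import expm

from .errors import (
    IdentifiabilityError,
    InvalidStepError,
    NoOperatingPointError,
    StateError,
)

__all__ = [
    "MechParams",
    "HydraulicParams",
    "PumpState",
    "BenchDataset",
    "mech_discretize",
    "mech_init",
    "mech_step",
    "hydraulic_step",
    "hydraulic_rhs",
    "static_head",
    "steady_flow",
    "identify_hydraulic",
    "IdentificationReport",
]

BENCH_COLUMNS = ("t_s", "n_rpm", "Q_lpm", "dP_mmHg")


@dataclass(frozen=True)
class MechParams:
    """Closed-loop speed dynamics: 1 / (k2*s^2 + k1*s + 1) * exp(-dead_time*s).

    The numerator is fixed to 1, so the DC gain is exactly unity: a constant
    reference speed is tracked without steady-state error.
    """

    k2: float = 3.3e-06  # s^2
    k1: float = 0.0043  # s
    dead_time: float = 0.002  # s

    def __post_init__(self) -> None:
        if not (self.k2 > 0 and self.k1 > 0):
            raise ValueError("k2 and k1 must be positive")
        if self.dead_time < 0:
            raise ValueError("dead_time must be non-negative")

    @property
    def damping_ratio(self) -> float:
        return self.k1 / (2.0 * np.sqrt(self.k2))


@dataclass(frozen=True)
class HydraulicParams:
    """Coefficients of the pump pressure-flow ODE (Sputnik1 defaults).

    Units: L mmHg*s*min/L, a mmHg*min/L, b mmHg/rpm^2,
    c mmHg*min^x/(L^x*rpm^y); x and y are integer exponents in [-2, 4].
    """

    L: float = 0.74
    a: float = -7.71
    b: float = 1.86e-06
    c: float = -5.49e-13
    x: int = 2
    y: int = 3

    def __post_init__(self) -> None:
        if self.L <= 0:
            raise ValueError("inertance L must be positive")
        for name, v in (("x", self.x), ("y", self.y)):
            if int(v) != v or not (-2 <= v <= 4):
                raise ValueError(f"exponent {name} must be an integer in [-2, 4]")


@dataclass
class PumpState:
    """Joint state of the mechanical and hydraulic subsystems."""

    n: float  # actual speed, rpm
    mech_internal: np.ndarray  # 2-vector internal PT2 state
    delay_buffer: np.ndarray  # past n_ref samples, oldest first
    Q: float  # pump flow, L/min
    _buf_idx: int = 0

    def copy(self) -> "PumpState":
        return PumpState(
            n=self.n,
            mech_internal=self.mech_internal.copy(),
            delay_buffer=self.delay_buffer.copy(),
            Q=self.Q,
            _buf_idx=self._buf_idx,
        )


@dataclass(frozen=True)
class BenchDataset:
    """Uniformly sampled hydraulic bench records (t, n, Q, dP)."""

    t: np.ndarray  # s
    n: np.ndarray  # rpm
    Q: np.ndarray  # L/min
    dP: np.ndarray  # mmHg

    def __post_init__(self) -> None:
        t = np.asarray(self.t, dtype=float)
        if t.ndim != 1 or len(t) < 3:
            raise ValueError("bench dataset needs at least 3 samples")
        dt = np.diff(t)
        if np.any(dt <= 0):
            raise ValueError("bench time must be strictly increasing")
        if not np.allclose(dt, dt[0], rtol=1e-6, atol=1e-12):
            raise ValueError("bench sampling must be uniform")
        for name in ("n", "Q", "dP"):
            if len(getattr(self, name)) != len(t):
                raise ValueError(f"column {name} length mismatch")

    @property
    def dt(self) -> float:
        return float(self.t[1] - self.t[0])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"t_s": self.t, "n_rpm": self.n, "Q_lpm": self.Q, "dP_mmHg": self.dP}
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "BenchDataset":
        missing = set(BENCH_COLUMNS) - set(df.columns)
        if missing:
            raise ValueError(f"bench CSV missing columns: {sorted(missing)}")
        return cls(
            t=df["t_s"].to_numpy(float),
            n=df["n_rpm"].to_numpy(float),
            Q=df["Q_lpm"].to_numpy(float),
            dP=df["dP_mmHg"].to_numpy(float),
        )

    @classmethod
    def read_csv(cls, path) -> "BenchDataset":
        return cls.from_frame(pd.read_csv(path))

    def write_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Mechanical subsystem
# ---------------------------------------------------------------------------


def mech_discretize(p: MechParams, dt: float) -> tuple[np.ndarray, np.ndarray]:
    """Exact zero-order-hold discretization of the PT2 part.

    Continuous state-space with output n = x1:
        x1' = x2
        x2' = (u - x1 - k1*x2) / k2
    """
    if dt <= 0:
        raise InvalidStepError("dt must be positive")
    A = np.array([[0.0, 1.0], [-1.0 / p.k2, -p.k1 / p.k2]])
    B = np.array([[0.0], [1.0 / p.k2]])
    # Van Loan block-matrix trick for (Ad, Bd)
    M = np.zeros((3, 3))
    M[:2, :2] = A * dt
    M[:2, 2:] = B * dt
    E = expm(M)
    return E[:2, :2], E[:2, 2]


def mech_init(n0: float, dt: float, p: MechParams = MechParams()) -> PumpState:
    """State matched to a steady reference speed n0 (delay buffer pre-filled)."""
    if dt <= 0:
        raise InvalidStepError("dt must be positive")
    nbuf = max(1, int(round(p.dead_time / dt))) if p.dead_time > 0 else 0
    buf = np.full(nbuf, float(n0))
    return PumpState(
        n=float(n0),
        mech_internal=np.array([float(n0), 0.0]),
        delay_buffer=buf,
        Q=0.0,
    )


def mech_step(state: PumpState, n_ref: float, dt: float, p: MechParams) -> PumpState:
    """Advance the delayed second-order speed response by one step.

    The dead time is realized as a ring buffer of round(dead_time/dt)
    reference samples; the PT2 recurrence is the exact ZOH discretization,
    so a steady reference is tracked exactly (unity DC gain).
    """
    if dt <= 0:
        raise InvalidStepError("dt must be positive")
    nbuf = max(1, int(round(p.dead_time / dt))) if p.dead_time > 0 else 0
    if len(state.delay_buffer) != nbuf:
        raise StateError(
            f"delay buffer length {len(state.delay_buffer)} does not match "
            f"round(dead_time/dt) = {nbuf}; initialize with mech_init"
        )
    out = state.copy()
    if nbuf:
        # pop the delayed sample, push the new reference
        u = out.delay_buffer[out._buf_idx]
        out.delay_buffer[out._buf_idx] = float(n_ref)
        out._buf_idx = (out._buf_idx + 1) % nbuf
    else:
        u = float(n_ref)
    Ad, Bd = _mech_matrices(p, dt)
    x0, x1 = out.mech_internal
    out.mech_internal[0] = Ad[0, 0] * x0 + Ad[0, 1] * x1 + Bd[0] * u
    out.mech_internal[1] = Ad[1, 0] * x0 + Ad[1, 1] * x1 + Bd[1] * u
    out.n = float(out.mech_internal[0])
    return out


_MECH_CACHE: dict[tuple[float, float, float], tuple[np.ndarray, np.ndarray]] = {}


def _mech_matrices(p: MechParams, dt: float) -> tuple[np.ndarray, np.ndarray]:
    key = (p.k2, p.k1, dt)
    got = _MECH_CACHE.get(key)
    if got is None:
        got = mech_discretize(p, dt)
        _MECH_CACHE[key] = got
    return got


# ---------------------------------------------------------------------------
# Hydraulic subsystem
# ---------------------------------------------------------------------------


def static_head(Q: float, n: float, p: HydraulicParams = HydraulicParams()) -> float:
    """Steady-state head pressure a*Q + b*n^2 + c*Q^x*n^y (mmHg)."""
    return p.a * Q + p.b * n**2 + p.c * Q ** p.x * float(n) ** p.y


def hydraulic_rhs(Q: float, n: float, dP: float, p: HydraulicParams) -> float:
    """dQ/dt in (L/min)/s."""
    return (static_head(Q, n, p) - dP) / p.L


def hydraulic_step(
    state: PumpState, n: float, dP: float, dt: float, p: HydraulicParams
) -> PumpState:
    """One explicit-Euler step of the pump flow ODE."""
    if dt <= 0:
        raise InvalidStepError("dt must be positive")
    if not (math.isfinite(n) and math.isfinite(dP) and math.isfinite(state.Q)):
        raise FloatingPointError("non-finite hydraulic input")
    out = state.copy()
    out.Q = state.Q + dt * hydraulic_rhs(state.Q, n, dP, p)
    if not math.isfinite(out.Q):
        raise FloatingPointError("hydraulic integration diverged")
    return out


def steady_flow(n: float, dP: float, p: HydraulicParams = HydraulicParams()) -> float:
    """Static inversion of the pump curve for x = 2: flow at (n, dP).

    Solves c*n^y * Q^2 + a*Q + (b*n^2 - dP) = 0 and returns the root that is
    continuous with the linear solution (dP - b*n^2)/a as c -> 0, i.e. the
    physical operating branch.
    """
    if p.x != 2:
        raise NotImplementedError("steady_flow implemented for the x = 2 dialect")
    A = p.c * float(n) ** p.y
    B = p.a
    C = p.b * n**2 - dP
    if A == 0.0:
        if B == 0.0:
            raise NoOperatingPointError("degenerate static curve (a = c = 0)")
        return -C / B
    disc = B * B - 4.0 * A * C
    if disc < 0:
        raise NoOperatingPointError(
            f"no real operating point at n={n} rpm, dP={dP} mmHg"
        )
    q = -(B + np.sign(B) * np.sqrt(disc)) / 2.0
    # roots are q/A and C/q; C/q is the branch continuous in c at c = 0
    return C / q


# ---------------------------------------------------------------------------
# Identification
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class IdentificationReport:
    """Per-(x, y) fit diagnostics and the selected hydraulic parameters."""

    params: HydraulicParams
    rmse_flow: float  # L/min, of the selected set
    rmse_dp: float  # mmHg, of the selected set
    table: pd.DataFrame  # columns x, y, L, a, b, c, rmse_dp, rmse_flow


def _finite_differences(Q: np.ndarray, dt: float) -> np.ndarray:
    """dQ/dt by central differences (4th-order interior), one-sided ends."""
    n = len(Q)
    d = np.empty(n)
    if n >= 5:
        d[2:-2] = (Q[:-4] - 8 * Q[1:-3] + 8 * Q[3:-1] - Q[4:]) / (12 * dt)
        d[1] = (Q[2] - Q[0]) / (2 * dt)
        d[-2] = (Q[-1] - Q[-3]) / (2 * dt)
    else:
        d[1:-1] = (Q[2:] - Q[:-2]) / (2 * dt)
    d[0] = (Q[1] - Q[0]) / dt
    d[-1] = (Q[-1] - Q[-2]) / dt
    return d


def _simulate_flow(
    data: BenchDataset, p: HydraulicParams, Q0: float
) -> np.ndarray:
    """Re-simulate flow by integrating the ODE against measured (n, dP)."""
    Q = np.empty(len(data.t))
    Q[0] = Q0
    dt = data.dt
    eps = 1e-9
    for i in range(len(Q) - 1):
        q = Q[i]
        if p.x < 0 and abs(q) < eps:
            q = eps
        dQ = (p.a * q + p.b * data.n[i] ** 2 + p.c * q ** p.x * data.n[i] ** p.y
              - data.dP[i]) / p.L
        Q[i + 1] = Q[i] + dt * dQ
        if not np.isfinite(Q[i + 1]) or abs(Q[i + 1]) > 1e6:
            Q[i + 1:] = np.nan
            break
    return Q


def identify_hydraulic(
    data: BenchDataset,
    x_grid: Iterable[int] = range(-2, 5),
    y_grid: Iterable[int] = range(-2, 5),
) -> IdentificationReport:
    """Identify (L, a, b, c) per (x, y) by linear least squares, select by flow RMSE.

    The ODE is rearranged to dP = a*Q + b*n^2 + c*Q^x*n^y - L*dQ/dt with
    dQ/dt obtained by finite differences, giving a problem linear in the four
    coefficients.  For each exponent pair the head-pressure residual is
    minimized; the candidate model is then re-simulated (flow integration
    against measured head pressure) and the pair with the smallest flow RMSE
    wins.
    """
    if np.ptp(data.n) < 1e-9 or np.ptp(data.Q) < 1e-9:
        raise IdentifiabilityError(
            "bench data must span multiple speeds and flows to identify the model"
        )
    dQdt = _finite_differences(np.asarray(data.Q, float), data.dt)
    rows = []
    best = None
    for x in x_grid:
        for y in y_grid:
            with np.errstate(divide="ignore", invalid="ignore"):
                cterm = np.asarray(data.Q, float) ** x * np.asarray(data.n, float) ** y
            mask = np.isfinite(cterm)
            if mask.sum() < 8:
                continue
            X = np.column_stack(
                [data.Q[mask], data.n[mask] ** 2, cterm[mask], -dQdt[mask]]
            )
            # unit-norm column scaling: exponent columns span ~15 orders of
            # magnitude, unscaled QR would lose the small coefficients
            norms = np.linalg.norm(X, axis=0)
            if np.any(norms == 0) or np.linalg.matrix_rank(X / norms) < 4:
                continue
            coef, *_ = np.linalg.lstsq(X / norms, data.dP[mask], rcond=None)
            coef = coef / norms
            a, b, c, L = coef
            if L <= 0:
                continue
            resid = X @ coef - data.dP[mask]
            rmse_dp = float(np.sqrt(np.mean(resid**2)))
            try:
                p = HydraulicParams(L=L, a=a, b=b, c=c, x=x, y=y)
            except ValueError:
                continue
            Qsim = _simulate_flow(data, p, float(data.Q[0]))
            ok = np.isfinite(Qsim)
            if ok.sum() < len(Qsim):
                rmse_q = np.inf
            else:
                rmse_q = float(np.sqrt(np.mean((Qsim - data.Q) ** 2)))
            rows.append(
                dict(x=x, y=y, L=L, a=a, b=b, c=c, rmse_dp=rmse_dp, rmse_flow=rmse_q)
            )
            if best is None or rmse_q < best[0]:
                best = (rmse_q, rmse_dp, p)
    if best is None:
        raise IdentifiabilityError("no exponent pair produced an identifiable fit")
    table = pd.DataFrame(rows).sort_values("rmse_flow").reset_index(drop=True)
    return IdentificationReport(
        params=best[2], rmse_flow=best[0], rmse_dp=best[1], table=table
    )
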