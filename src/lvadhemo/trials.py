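"""Hemolysis-trial analysis: HRI computation, standardization, robust fitting.

A hemolysis trial runs one pump at a constant (speed, flow) operating point
for several hours in a closed blood loop; plasma-free hemoglobin (pfHb),
total hemoglobin (Hb) and hematocrit (HCT) are sampled hourly.  The
hemolysis rate index for each sampling interval is

    HRI [%*mL/h] = (dpfHb / Hb) * 100 * (V / dT) * (100 - HCT) / 100,

with pfHb and Hb first brought to a common concentration unit (pfHb is
reported in mg/dL, Hb in g/dL), V the current loop volume in mL and dT the
interval length in hours.  The trial HRI is the mean over its intervals.

When several pumps of the same type are combined, each device's HRI values
are standardized (divided by the device mean, multiplied by the common
scaling constant HRI_bar) to remove specimen-to-specimen offsets before the
power law is fitted by iteratively reweighted (bisquare) nonlinear least
squares on the linear scale.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .errors import (
    ConvergenceError,
    InsufficientDataError,
    StandardizationError,
)
from .hemolysis import PowerLawParams

__all__ = [
    "BloodSample",
    "TrialRecord",
    "FitResult",
    "hri_from_samples",
    "standardize",
    "fit_power_law",
    "mih_to_hri",
    "trials_to_frame",
    "trials_from_frame",
    "read_trials_csv",
    "write_trials_csv",
]

TRIAL_COLUMNS = (
    "device_id",
    "n_rpm",
    "Q_lpm",
    "t_h",
    "pfHb_mg_dl",
    "Hb_g_dl",
    "HCT_pct",
    "V_ml",
)

BISQUARE_TUNING = 4.685
MAD_TO_SIGMA = 0.6745  # MAD of a normal sample / sigma


@dataclass(frozen=True)
class BloodSample:
    """One hourly loop measurement."""

    t: float  # h since trial start
    pfHb: float  # mg/dL
    Hb: float  # g/dL
    HCT: float  # %, 0-100
    V: float  # current loop volume, mL

    def __post_init__(self) -> None:
        if not (0 < self.HCT < 100):
            raise ValueError("HCT must be in (0, 100) %")
        if self.pfHb < 0:
            raise ValueError("pfHb must be non-negative")
        if self.Hb <= 0 or self.V <= 0:
            raise ValueError("Hb and V must be positive")


@dataclass
class TrialRecord:
    """One constant-condition hemolysis trial of one device."""

    device_id: str
    n: float  # rpm
    Q: float  # L/min
    samples: Sequence[BloodSample] = field(default_factory=list)
    hri: float | None = None  # %*mL/h, derived

    def __post_init__(self) -> None:
        t = [s.t for s in self.samples]
        if any(b <= a for a, b in zip(t, t[1:])):
            raise ValueError("samples must be strictly time-ordered")


def hri_from_samples(trial: TrialRecord) -> tuple[np.ndarray, float]:
    """Per-interval HRI values and their mean for one trial.

    Uses consecutive-sample pfHb differences; V and HCT of each interval are
    the interval-start measurements.  Negative intervals (assay noise) are
    kept but reported with a warning.  Returns ``(per_interval, mean)``.
    """
    if len(trial.samples) < 2:
        raise InsufficientDataError("need at least two blood samples")
    out = []
    for s0, s1 in zip(trial.samples, trial.samples[1:]):
        d_pfhb = s1.pfHb - s0.pfHb  # mg/dL
        dT = s1.t - s0.t  # h
        hb_mg_dl = s0.Hb * 1000.0  # g/dL -> mg/dL
        hri = (d_pfhb / hb_mg_dl) * 100.0 * (s0.V / dT) * (100.0 - s0.HCT) / 100.0
        out.append(hri)
    per_interval = np.array(out)
    if np.any(per_interval < 0):
        warnings.warn(
            f"trial {trial.device_id}@({trial.n} rpm, {trial.Q} L/min): "
            f"{int(np.sum(per_interval < 0))} interval(s) with negative HRI "
            "(pfHb decreased; measurement noise)",
            stacklevel=2,
        )
    return per_interval, float(np.mean(per_interval))


def standardize(
    trials: Sequence[TrialRecord], HRI_bar: float = PowerLawParams().HRI_bar
) -> list[TrialRecord]:
    """Remove per-device offsets: HRI <- HRI / mean_device(HRI) * HRI_bar.

    After standardization every device's mean HRI equals HRI_bar, so devices
    with systematically different hemolysis magnitude collapse onto one
    response surface.  Trials must carry a derived ``hri`` (see
    :func:`hri_from_samples`).
    """
    if any(t.hri is None for t in trials):
        raise ValueError("all trials need a derived hri before standardization")
    means: dict[str, float] = {}
    for dev in {t.device_id for t in trials}:
        vals = [t.hri for t in trials if t.device_id == dev]
        m = float(np.mean(vals))
        if not np.isfinite(m) or m <= 0:
            raise StandardizationError(f"device {dev} has non-positive mean HRI")
        means[dev] = m
    return [replace(t, hri=t.hri / means[t.device_id] * HRI_bar) for t in trials]


@dataclass(frozen=True)
class FitResult:
    """Robust power-law fit with goodness-of-fit on unit weights."""

    params: PowerLawParams
    rmse: float  # %*mL/h
    r2: float
    weights: np.ndarray  # final bisquare weights, in [0, 1]
    n_iter: int

    def __post_init__(self) -> None:
        if self.r2 > 1 + 1e-12:
            raise ValueError("r2 cannot exceed 1")


def _model(theta: np.ndarray, Q, n, scale: PowerLawParams) -> np.ndarray:
    c2, a2, b2 = theta
    return (
        scale.HRI_bar * c2 * (Q / scale.Q_bar) ** a2 * (n / scale.n_bar) ** b2
    )


def _loglog_start(Q, n, hri, scale: PowerLawParams) -> np.ndarray:
    """Ordinary log-log linear regression as robust starting point."""
    pos = hri > 0
    if pos.sum() < 3:
        return np.array([1.0, -0.5, 5.0])
    X = np.column_stack(
        [np.ones(pos.sum()), np.log(Q[pos] / scale.Q_bar), np.log(n[pos] / scale.n_bar)]
    )
    beta, *_ = np.linalg.lstsq(X, np.log(hri[pos] / scale.HRI_bar), rcond=None)
    return np.array([np.exp(beta[0]), beta[1], beta[2]])


def fit_power_law(
    trials: Sequence[TrialRecord],
    scale: PowerLawParams = PowerLawParams(),
    max_iter: int = 100,
    tol: float = 1e-5,
) -> FitResult:
    """Fit (c2, a2, b2) by bisquare-weighted nonlinear least squares.

    Residuals are formed on the linear (untransformed) HRI scale.  The
    robust loop alternates a weighted Levenberg-Marquardt solve with a
    bisquare weight update (tuning constant 4.685, scale from the residual
    MAD); it stops when the parameters move less than ``tol`` (relative).
    RMSE and R^2 are reported on the data with unit weights.
    """
    if any(t.hri is None for t in trials):
        raise ValueError("all trials need a derived hri before fitting")
    Q = np.array([t.Q for t in trials], float)
    n = np.array([t.n for t in trials], float)
    hri = np.array([t.hri for t in trials], float)
    if len({(q, s) for q, s in zip(Q, n)}) < 4:
        raise InsufficientDataError("need at least 4 distinct (Q, n) points")
    if np.ptp(Q) < 1e-12 or np.ptp(n) < 1e-12:
        warnings.warn(
            "design does not span both flow and speed; exponents are not "
            "jointly identifiable",
            stacklevel=2,
        )

    theta = _loglog_start(Q, n, hri, scale)
    w = np.ones(len(hri))
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        sw = np.sqrt(w)

        def resid(th):
            return sw * (_model(th, Q, n, scale) - hri)

        sol = least_squares(resid, theta, method="lm", xtol=1e-14, ftol=1e-14)
        theta_new = sol.x
        r = _model(theta_new, Q, n, scale) - hri
        tiny = 1e-12 * max(1.0, float(np.max(np.abs(hri))))
        s = np.median(np.abs(r - np.median(r))) / MAD_TO_SIGMA
        if s < tiny:
            # MAD degenerates when most points fit exactly; fall back to the
            # mean absolute residual so isolated outliers still get cut off
            s = float(np.mean(np.abs(r))) / 0.8
        if s < tiny:
            w_new = np.ones_like(w)  # genuinely perfect fit
        else:
            u = r / (BISQUARE_TUNING * s)
            w_new = np.where(np.abs(u) < 1, (1 - u**2) ** 2, 0.0)
        moved = np.max(np.abs(theta_new - theta) / np.maximum(1e-12, np.abs(theta)))
        theta, w = theta_new, w_new
        if moved < tol:
            break
    else:
        raise ConvergenceError(
            f"robust fit did not converge in {max_iter} iterations "
            f"(last parameter move {moved:.2e})"
        )

    r = _model(theta, Q, n, scale) - hri
    rmse = float(np.sqrt(np.mean(r**2)))
    ss_tot = float(np.sum((hri - hri.mean()) ** 2))
    r2 = 1.0 - float(np.sum(r**2)) / ss_tot if ss_tot > 0 else 1.0
    params = replace(scale, c2=float(theta[0]), a2=float(theta[1]), b2=float(theta[2]))
    return FitResult(params=params, rmse=rmse, r2=r2, weights=w, n_iter=n_iter)


def mih_to_hri(mih: float, Q_const: float) -> float:
    """Convert a Modified Index of Hemolysis to HRI: mih * Q_const * 6."""
    if Q_const <= 0:
        raise ValueError("Q_const must be positive")
    return mih * Q_const * 6.0


# ---------------------------------------------------------------------------
# CSV round trip (schema: device_id,n_rpm,Q_lpm,t_h,pfHb_mg_dl,Hb_g_dl,HCT_pct,V_ml)
# ---------------------------------------------------------------------------


def trials_to_frame(trials: Sequence[TrialRecord]) -> pd.DataFrame:
    rows = []
    for t in trials:
        for s in t.samples:
            rows.append(
                dict(
                    device_id=t.device_id,
                    n_rpm=t.n,
                    Q_lpm=t.Q,
                    t_h=s.t,
                    pfHb_mg_dl=s.pfHb,
                    Hb_g_dl=s.Hb,
                    HCT_pct=s.HCT,
                    V_ml=s.V,
                )
            )
    return pd.DataFrame(rows, columns=list(TRIAL_COLUMNS))


def trials_from_frame(df: pd.DataFrame) -> list[TrialRecord]:
    missing = set(TRIAL_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"trial CSV missing columns: {sorted(missing)}")
    trials = []
    for (dev, n, q), grp in df.groupby(["device_id", "n_rpm", "Q_lpm"], sort=False):
        grp = grp.sort_values("t_h")
        samples = [
            BloodSample(
                t=r.t_h, pfHb=r.pfHb_mg_dl, Hb=r.Hb_g_dl, HCT=r.HCT_pct, V=r.V_ml
            )
            for r in grp.itertuples()
        ]
        trials.append(TrialRecord(device_id=str(dev), n=float(n), Q=float(q),
                                  samples=samples))
    return trials


def read_trials_csv(path) -> list[TrialRecord]:
    return trials_from_frame(pd.read_csv(path))


def write_trials_csv(trials: Sequence[TrialRecord], path) -> None:
    trials_to_frame(trials).to_csv(path, index=False)
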