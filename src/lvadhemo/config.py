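"""Structured YAML configuration for all model parameter sets.

A single file with optional sections ``pump`` (``mech`` and ``hyd``
sub-sections), ``power_law``, ``geometry``, ``cvs``, ``profile`` and
``sweep``; any omitted key falls back to the built-in Sputnik1 /
heart-failure-baseline defaults.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields
from pathlib import Path
from typing import Any

import yaml

from .cvs import CVSParams
from .hemolysis import ImpellerGeometry, PowerLawParams
from .profiles import ModulationSpec
from .pump import HydraulicParams, MechParams

__all__ = ["Config", "load_config", "save_config"]

_GEOM_KEYS = {"Vi_mL": "Vi", "li_mm": "li"}


@dataclass(frozen=True)
class SweepConfig:
    """Grids of the speed-modulation sweep."""

    mean_speeds: tuple = (6500.0, 7500.0, 8500.0)
    amplitudes: tuple = tuple(float(a) for a in range(500, 3001, 500))
    cutoffs: tuple = (20.0, 5.0, 2.0)
    duty_step: float = 0.05
    phase_step: float = 0.05


@dataclass(frozen=True)
class Config:
    mech: MechParams = field(default_factory=MechParams)
    hyd: HydraulicParams = field(default_factory=HydraulicParams)
    power_law: PowerLawParams = field(default_factory=PowerLawParams)
    geometry: ImpellerGeometry = field(default_factory=ImpellerGeometry)
    cvs: CVSParams = field(default_factory=CVSParams)
    profile: ModulationSpec | None = None
    sweep: SweepConfig = field(default_factory=SweepConfig)
    dt: float = 0.0004


def _build(cls, data: dict[str, Any] | None):
    if not data:
        return cls()
    known = {f.name for f in fields(cls)}
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown {cls.__name__} keys: {sorted(unknown)}")
    return cls(**data)


def load_config(path: str | Path | None = None) -> Config:
    """Load a config file; with ``path=None`` return all defaults."""
    if path is None:
        return Config()
    raw = yaml.safe_load(Path(path).read_text()) or {}
    pump = raw.get("pump", {}) or {}
    geom_raw = {
        _GEOM_KEYS.get(k, k): v for k, v in (raw.get("geometry") or {}).items()
    }
    sweep_raw = raw.get("sweep") or {}
    for k in ("mean_speeds", "amplitudes", "cutoffs"):
        if k in sweep_raw:
            sweep_raw[k] = tuple(float(v) for v in sweep_raw[k])
    profile_raw = raw.get("profile")
    return Config(
        mech=_build(MechParams, pump.get("mech")),
        hyd=_build(HydraulicParams, pump.get("hyd")),
        power_law=_build(PowerLawParams, raw.get("power_law")),
        geometry=_build(ImpellerGeometry, geom_raw),
        cvs=_build(CVSParams, raw.get("cvs")),
        profile=_build(ModulationSpec, profile_raw) if profile_raw else None,
        sweep=_build(SweepConfig, sweep_raw),
        dt=float(raw.get("dt", 0.0004)),
    )


def save_config(cfg: Config, path: str | Path) -> None:
    def asdict(obj):
        return {f.name: getattr(obj, f.name) for f in fields(obj)}

    doc = {
        "dt": cfg.dt,
        "pump": {"mech": asdict(cfg.mech), "hyd": asdict(cfg.hyd)},
        "power_law": asdict(cfg.power_law),
        "geometry": {"Vi_mL": cfg.geometry.Vi, "li_mm": cfg.geometry.li},
        "cvs": asdict(cfg.cvs),
        "sweep": {
            "mean_speeds": list(cfg.sweep.mean_speeds),
            "amplitudes": list(cfg.sweep.amplitudes),
            "cutoffs": list(cfg.sweep.cutoffs),
            "duty_step": cfg.sweep.duty_step,
            "phase_step": cfg.sweep.phase_step,
        },
    }
    if cfg.profile is not None:
        doc["profile"] = asdict(cfg.profile)
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))
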