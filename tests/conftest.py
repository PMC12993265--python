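"""Shared fixtures: default parameter sets and expensive cached computations."""

from __future__ import annotations

import numpy as np
import pytest

from lvadhemo.hemolysis import (
    ImpellerGeometry,
    PowerLawParams,
    calibrate_f,
    reduce_params,
)
from lvadhemo.pump import HydraulicParams, MechParams

DT = 0.0004  # global hemolysis step time, s


@pytest.fixture(scope="session")
def plp() -> PowerLawParams:
    return PowerLawParams()


@pytest.fixture(scope="session")
def geom() -> ImpellerGeometry:
    return ImpellerGeometry()


@pytest.fixture(scope="session")
def rp(plp, geom):
    return reduce_params(plp, geom)


@pytest.fixture(scope="session")
def hyd() -> HydraulicParams:
    return HydraulicParams()


@pytest.fixture(scope="session")
def mech() -> MechParams:
    return MechParams()


@pytest.fixture(scope="session")
def correction_f(plp, geom) -> float:
    """Correction factor calibrated once at 0.5 L/min with the default step."""
    return calibrate_f(g=geom, dt=DT, p=plp)


@pytest.fixture(scope="session")
def rng() -> np.random.Generator:
    return np.random.default_rng(20240831)
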