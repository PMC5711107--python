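"""Shared fixtures: materials, beamline configurations and toy foils."""

import numpy as np
import pytest

from foilsim.beamline import BeamlineGeometry, GaussianFoilSpec, segment_gaussian_foil
from foilsim.config import SimulationConfig
from foilsim.materials import get_material


@pytest.fixture(scope="session")
def water():
    return get_material("water")


@pytest.fixture(scope="session")
def tantalum():
    return get_material("tantalum")


@pytest.fixture(scope="session")
def aluminum():
    return get_material("aluminum")


@pytest.fixture(scope="session")
def nickel():
    return get_material("nickel")


@pytest.fixture(scope="session")
def air():
    return get_material("air")


@pytest.fixture
def default_config() -> SimulationConfig:
    """The 13 MeV design-example configuration (80 um Ta primary,
    0.6 cm / 1.44 cm aluminum Gaussian secondary)."""
    return SimulationConfig()


@pytest.fixture
def geometry() -> BeamlineGeometry:
    return BeamlineGeometry(
        d_window_primary=5.0,
        d_primary_secondary=12.0,
        d_secondary_iso=88.0,
    )


@pytest.fixture
def gaussian_foil(aluminum):
    spec = GaussianFoilSpec(
        material=aluminum, t0=0.6, sigma=1.44, n_segments=16, r_max=3.65
    )
    return segment_gaussian_foil(spec)


@pytest.fixture
def thin_beam_config() -> SimulationConfig:
    """A narrow-beam variant whose z1 fluence is almost fully contained
    inside the secondary-foil radius (for conservation checks)."""
    cfg = SimulationConfig()
    cfg.primary_foil.thickness_cm = 0.002
    cfg.window.thickness_cm = 0.003
    return cfg
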