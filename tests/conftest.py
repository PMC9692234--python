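"""Shared fixtures: a few Monte Carlo runs reused across test modules."""

import numpy as np
import pytest
from hypothesis import settings

from ssadose.beam_model import BeamModel, sample_beamlet, energy_for_bp_depth
from ssadose.transport import simulate_configuration, transport_beamlet, GeometryStack
from ssadose.workflow import ssa_geometry, open_geometry

settings.register_profile("ci", deadline=None, derandomize=True)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def beam_model():
    return BeamModel()


@pytest.fixture(scope="session")
def pristine_result(beam_model):
    """Infinitesimal 160 MeV beamlet into bare water, nuclear model off."""
    src = sample_beamlet(beam_model, 160.0, 20_000, seed=101, infinitesimal=True)
    geom = GeometryStack(phantom_shape=(61, 61, 190))
    return transport_beamlet(src, geom, seed=202, nuclear=False)


@pytest.fixture(scope="session")
def ssa_pair(beam_model):
    """Paired with/without-aperture runs: tungsten r=3 mm, ASD 50 mm, BP 50 mm."""
    energy = energy_for_bp_depth(50.0, 45.0)
    src = sample_beamlet(beam_model, energy, 50_000, seed=303)
    geom = ssa_geometry("tungsten", 3.0, 50.0)
    return simulate_configuration(src, geom, seed=404, nuclear=True)
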