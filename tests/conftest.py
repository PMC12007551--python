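"""Shared fixtures: cells, waveforms and configs reused across test modules."""

import numpy as np
import pytest

from tmsresponse.cable_sim import MembraneModel, SimConfig
from tmsresponse.field_coupling import make_waveform
from tmsresponse.morphology import (
    discretize,
    generate_ball_and_stick,
    generate_synthetic_population,
)


@pytest.fixture(scope="session")
def mono_wave():
    return make_waveform("monophasic", dt=5.0)


@pytest.fixture(scope="session")
def cfg():
    return SimConfig()


@pytest.fixture(scope="session")
def mm():
    return MembraneModel()


@pytest.fixture(scope="session")
def bas_cm():
    """Discretized ball-and-stick reference cell (l=760 µm, d=15 µm)."""
    return discretize(generate_ball_and_stick(760.0, 15.0))


@pytest.fixture(scope="session")
def pyramidal_cells():
    return generate_synthetic_population(3, "pyramidal_like", 42)


@pytest.fixture(scope="session")
def branched_cm(pyramidal_cells):
    return discretize(pyramidal_cells[0])
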