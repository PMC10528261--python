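import dataclasses

import numpy as np
import pytest

from mwangio import forward, geometry


@pytest.fixture(scope="session")
def default_geom():
    return geometry.build_default_array()


@pytest.fixture(scope="session")
def small_geom():
    """2 TX + 2 RX on one ring: 4 channels, cheap to simulate."""
    return geometry.build_default_array(n_tx=2, n_rx=2, ring_z=(-0.05,))


@pytest.fixture(scope="session")
def phantom():
    return geometry.PhantomModel()


@pytest.fixture(scope="session")
def scenario1():
    return geometry.build_scenario(1)


@pytest.fixture(scope="session")
def mseq9():
    return forward.generate_msequence(9)


@pytest.fixture(scope="session")
def small_acq():
    """Short record: 255-chip sequence, 20 soundings over 25 s (2 periods)."""
    return forward.AcquisitionConfig(m_order=8, duration=25.0)


def static_scenario(scenario):
    """Copy of a scenario with every artery clipped (non-pulsating)."""
    arteries = tuple(
        dataclasses.replace(a, pulsating=False) for a in scenario.arteries
    )
    return dataclasses.replace(scenario, arteries=arteries)


@pytest.fixture(scope="session")
def single_scatterer_cube(default_geom, phantom):
    """Noiseless cube of one pulsating point scatterer at (2, 1, -5) cm."""
    artery = geometry.ArteryModel.with_amplitude((0.02, 0.01))
    sc = forward.ScattererResponse(
        position=(0.02, 0.01, -0.05),
        static_amplitude=0.69,
        modulation_gain=276.0,
        artery=artery,
    )
    acq = forward.AcquisitionConfig()
    cube = forward.simulate_from_scatterers([sc], default_geom, acq, medium=phantom)
    return cube
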