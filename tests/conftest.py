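"""Shared fixtures: small synthetic networks and short simulation configs.

Everything is generated programmatically with fixed seeds; no data files.
"""

import numpy as np
import pytest

import rwwfit as rf
from rwwfit.synth import default_theta


@pytest.fixture(scope="session")
def spec10():
    return rf.SynthSpec(n_nodes=10, seed=1)


@pytest.fixture(scope="session")
def connectome(spec10):
    return rf.make_connectome(spec10)


@pytest.fixture(scope="session")
def maps(spec10):
    return rf.make_maps(spec10)


@pytest.fixture(scope="session")
def theta_true(maps):
    return default_theta(maps, seed=1)


@pytest.fixture(scope="session")
def short_cfg():
    """60 s simulation, 30 s burn-in: enough for stable state averages."""
    return rf.SimConfig(TR=3.0, duration=60.0, burn_in=30.0, noise_seed=42)


@pytest.fixture(scope="session")
def desk_cfg():
    """Desk-scale analogue of the full protocol: 120 s, TR 3 s."""
    return rf.SimConfig(TR=3.0, duration=120.0, burn_in=30.0, noise_seed=42)


@pytest.fixture(scope="session")
def balanced_weights(connectome, maps, theta_true, short_cfg):
    """Regional weights for the ground-truth parameters after FIC."""
    w = rf.expand_regional_params(theta_true, maps)
    full, res = rf.run_fic(connectome, w, theta_true.G, short_cfg)
    assert res.converged.all()
    return full


@pytest.fixture(scope="session")
def single_node():
    return rf.Connectome(weights=np.zeros((1, 1)))
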