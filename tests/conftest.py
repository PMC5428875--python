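import numpy as np
import pytest

import samflex as sf
from samflex import layer_model as lm
from samflex import synthetic_data as sd


@pytest.fixture(scope="session")
def geometry():
    """The measurement cantilever: 500 × 100 × 1 μm silicon."""
    return sd.DEFAULT_GEOMETRY


@pytest.fixture(scope="session")
def ss_config():
    return lm.LayerConfig(kind="ssDNA", grafting_density=3.7e13)


@pytest.fixture(scope="session")
def ds_config():
    return lm.LayerConfig(kind="dsDNA", grafting_density=3.7e13)


@pytest.fixture
def rng():
    return np.random.default_rng(20260920)


def neutral_axis_effective_modulus(e_g, t_g, e_d, t_d):
    """Independent composite-beam oracle: locate the neutral axis of the
    two-layer cross-section, integrate E·z² for the bending stiffness per
    unit width, normalize by (t_g+t_d)³/12."""
    layers = [(e_g, 0.0, t_g), (e_d, t_g, t_g + t_d)]
    ea = sum(e * (z1 - z0) for e, z0, z1 in layers)
    z_n = sum(e * (z1 - z0) * (z0 + z1) / 2 for e, z0, z1 in layers) / ea
    ei = sum(e * ((z1 - z_n) ** 3 - (z0 - z_n) ** 3) / 3 for e, z0, z1 in layers)
    return ei / ((t_g + t_d) ** 3 / 12.0)
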