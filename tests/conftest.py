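import numpy as np
import pytest

from aneukit import make_domain


@pytest.fixture(scope="session")
def small_domain():
    """Coarse sac (radius 4 mm, neck 2 mm, 0.5 mm voxels) shared across tests."""
    return make_domain(sac_radius=4.0, neck_radius=2.0, spacing=0.5)


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)
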