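import numpy as np
import pytest

from ieloc.synthetic import make_icosphere, make_shaft_fixture


@pytest.fixture(scope="session")
def straight_shaft():
    """8-contact straight shaft, 3.5 mm pitch, 0.5 mm voxels, mild noise."""
    return make_shaft_fixture(n=8, spacing=3.5, seed=11)


@pytest.fixture(scope="session")
def arc_shaft():
    """12-contact arc, 80 mm curvature radius (typical worst-case shaft bend)."""
    return make_shaft_fixture(n=12, spacing=3.5, curvature_radius=80.0,
                              shape=(112, 112, 112), seed=12)


@pytest.fixture(scope="session")
def sphere50():
    """Radius-50 mm icosphere centered at the origin (pial-envelope stand-in)."""
    return make_icosphere(center=(0.0, 0.0, 0.0), radius=50.0, subdivisions=3)


@pytest.fixture()
def rng():
    return np.random.default_rng(20260922)
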