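import numpy as np
import pytest

from lungbud.geometry import LungGeometry, build_geometry
from lungbud.mesh import make_mesh
from lungbud.params import ParamSet


@pytest.fixture(scope="session")
def reference_params():
    return ParamSet()


@pytest.fixture(scope="session")
def tissue_mesh():
    """Tissue-only no-buffer mesh for conservation and solver tests."""
    return make_mesh(build_geometry(LungGeometry(Lfar=0.0, h0=2.0)), 0.2)


@pytest.fixture(scope="session")
def buffered_mesh():
    """Small open-domain mesh (modest buffer, coarse)."""
    return make_mesh(build_geometry(LungGeometry(Lfar=6.0, h0=2.0)), 0.3)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
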