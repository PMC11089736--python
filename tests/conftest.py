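import numpy as np
import pytest

from cardiotwin import cohort as co
from cardiotwin import forward_model as fm
from cardiotwin import registry as reg


@pytest.fixture(scope="session")
def homogeneous_registry():
    return reg.build_homogeneous_registry()


@pytest.fixture(scope="session")
def registry6(homogeneous_registry):
    return reg.apply_segmentation(homogeneous_registry, 6)


@pytest.fixture(scope="session")
def registry18(homogeneous_registry):
    return reg.apply_segmentation(homogeneous_registry, 18)


@pytest.fixture(scope="session")
def reference_params6(registry6):
    return fm.reference_parameters(registry6)


@pytest.fixture(scope="session")
def reference_sim6(reference_params6):
    return fm.simulate(reference_params6)


@pytest.fixture(scope="session")
def heterogeneous_sim6(reference_params6):
    p = reference_params6.copy()
    p.segmental["dT"][:] = [0.0, 20.0, 40.0, 60.0, 80.0, 100.0]
    return fm.simulate(p)


@pytest.fixture(scope="session")
def lbbb_patient6():
    """Noise-free 6-segment LBBB-like virtual patient."""
    return co.generate_patient("LBBB-only", 6, seed=42,
                               noise=co.NoiseConfig(level=0.0))


@pytest.fixture(scope="session")
def healthy_patient6():
    return co.generate_patient("healthy", 6, seed=7,
                               noise=co.NoiseConfig(level=0.0))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
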