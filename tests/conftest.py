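import numpy as np
import pytest

from flexitomo.phantoms import make_asymmetric_volume, make_globular_structure
from flexitomo.nma import compute_modes_rtb


@pytest.fixture(scope="session")
def ref1656():
    """Synthetic 1656-atom globular reference (enzyme-sized)."""
    return make_globular_structure(1656, seed=0)


@pytest.fixture(scope="session")
def modes1656(ref1656):
    return compute_modes_rtb(ref1656, residues_per_block=2, cutoff=8.0, n_modes=12)


@pytest.fixture(scope="session")
def small_ref():
    """400-atom structure for fast unit tests."""
    return make_globular_structure(400, seed=1)


@pytest.fixture(scope="session")
def small_modes(small_ref):
    return compute_modes_rtb(small_ref, residues_per_block=1, cutoff=8.0, n_modes=12)


@pytest.fixture
def phantom32():
    return make_asymmetric_volume(32, 2.0, seed=3)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
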