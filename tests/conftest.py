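import numpy as np
import pytest

from flyeye.simulate import DegenerationSpec, LatticeSpec, generate_eye_image


@pytest.fixture(scope="session")
def clean_lattice():
    """Undisturbed 5x5 hexagonal array and its ground truth."""
    lattice = LatticeSpec(n_rows=5, n_cols=5, spacing=14.0, dot_radius=4.0)
    img, truth = generate_eye_image(lattice, DegenerationSpec(seed=0))
    return lattice, img, truth


@pytest.fixture(scope="session")
def big_lattice():
    """9x9 array large enough to keep interior ommatidia after ROI pruning."""
    lattice = LatticeSpec(n_rows=9, n_cols=9, spacing=13.0, dot_radius=4.0)
    img, truth = generate_eye_image(lattice, DegenerationSpec(seed=0))
    return lattice, img, truth


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
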