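import numpy as np
import pytest

from stromapy import TissueSpec, generate_tissue


@pytest.fixture(scope="session")
def small_spec():
    """A fast 256x256 field with ~120 cells for unit tests."""
    return TissueSpec(
        image_size_px=(256, 256),
        pixel_size_um=1.0,
        n_cells=120,
        stroma_fraction=0.3,
        seed=7,
    )


@pytest.fixture(scope="session")
def small_tissue(small_spec):
    return generate_tissue(small_spec)


@pytest.fixture()
def rng():
    return np.random.default_rng(123)
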