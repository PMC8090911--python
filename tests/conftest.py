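import numpy as np
import pytest

from perilyso.synthcells import FieldSpec, render_cell_field


@pytest.fixture(scope="session")
def noise_free_field():
    """One deterministic noise-free field with its ground truth."""
    spec = FieldSpec(seed=11, noise_sd=0.0)
    return spec, *render_cell_field(spec)


@pytest.fixture(scope="session")
def default_field():
    """One deterministic field at generator defaults (with noise)."""
    spec = FieldSpec(seed=5)
    return spec, *render_cell_field(spec)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
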