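import numpy as np
import pytest

from tgnscreen import FieldSpec, ScreenSpec, generate_field, generate_screen


@pytest.fixture(scope="session")
def noiseless_field():
    """Small noiseless field with a designed 2:1 inside/outside cargo ratio."""
    spec = FieldSpec(image_size=(384, 384), n_cells=10, noise_sd=0.0,
                     target_ratio=2.0, seed=11)
    img, truth = generate_field(spec)
    return spec, img, truth


@pytest.fixture(scope="session")
def default_screen():
    """Simulated screen at the default (printed) control parameters."""
    spec = ScreenSpec(n_plates=4, seed=7)
    wells, truth = generate_screen(spec)
    return spec, wells, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
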