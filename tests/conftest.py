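import numpy as np
import pytest

from ribmnlm import NoiseSpec, add_noise, default_phantom_spec, make_phantom


@pytest.fixture(scope="session")
def random_patches():
    """100 seeded random 15x15 patches on the 0-255 scale."""
    rng = np.random.default_rng(1234)
    return [rng.uniform(0.0, 255.0, (15, 15)) for _ in range(100)]


@pytest.fixture(scope="session")
def phantom48():
    """Small clean/noisy phantom pair for pipeline-level tests."""
    clean = make_phantom(default_phantom_spec(48, 48, seed=7))
    noisy = add_noise(clean, NoiseSpec(model="additive_gaussian", sigma=20.0, seed=3))
    return clean, noisy
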