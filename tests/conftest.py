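import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from triq.synthetic import SyntheticSpec, generate_ion_image


@pytest.fixture
def rng():
    return np.random.default_rng(20260921)


@pytest.fixture
def skewed_image(rng):
    """Right-skewed image with sparse extreme outliers.

    Mimics a raw MSI slice: a gamma bulk plus a few pixels two orders of
    magnitude above it, so naive min-max quantization packs nearly all
    pixels into the lowest levels.
    """
    a = rng.gamma(2.0, 100.0, size=(60, 60))
    flat = a.ravel()
    idx = rng.choice(flat.size, size=12, replace=False)
    flat[idx] = rng.uniform(30_000.0, 70_000.0, size=12)
    return a


@pytest.fixture
def standard_fixture():
    """Default synthetic ion image with ground truth (region + outliers)."""
    spec = SyntheticSpec(seed=7)
    img, region = generate_ion_image(spec)
    return spec, img, region
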