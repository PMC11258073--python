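"""Shared fixtures: programmatically generated phantoms at two sizes.

``small_spec`` is a reduced geometry used where the test only needs a valid
phantom quickly; default-geometry phantoms are session-scoped so their cost
is paid once.
"""

import numpy as np
import pytest

from noisekit import PhantomSpec, generate_phantom


def small_spec(**overrides) -> PhantomSpec:
    kw = dict(shape=(24, 48, 96), aorta_radius=12.0, lm_length=15.0,
              rca_length=15.0, seed=0)
    kw.update(overrides)
    return PhantomSpec(**kw)


@pytest.fixture(scope="session")
def phantom_noisy():
    """Default-geometry phantom with injected noise SD 35 HU."""
    return generate_phantom(PhantomSpec(aorta_attenuation=450.0,
                                        noise_sd=35.0, seed=1))


@pytest.fixture(scope="session")
def phantom_clean():
    """Zero-noise phantom: every vessel voxel is exactly the set attenuation."""
    return generate_phantom(PhantomSpec(aorta_attenuation=450.0,
                                        noise_sd=0.0, seed=1))


@pytest.fixture(scope="session")
def small_phantom():
    return generate_phantom(small_spec(noise_sd=30.0, seed=3))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
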