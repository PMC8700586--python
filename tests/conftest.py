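import numpy as np
import pytest

from fwdti import PhantomSpec, default_scheme, generate_phantom

#: compact lesion geometry for fast unit-test phantoms (24 x 24 x 8 grid)
SMALL_KW = dict(
    grid_shape=(24, 24, 8),
    lesion_center=(9.0, 14.0, 4.0),
    radii_total=(5.0, 4.5, 2.8),
    radii_enhancing=(3.2, 3.0, 2.0),
    radii_necrotic=(1.8, 1.5, 1.2),
)


@pytest.fixture(scope="session")
def scheme():
    return default_scheme()


@pytest.fixture(scope="session")
def small_noiseless():
    """Small noiseless phantom shared by fit tests (expensive to refit)."""
    spec = PhantomSpec(snr=float("inf"), seed=7, **SMALL_KW)
    dwi, sch, masks, truth = generate_phantom(spec)
    return spec, dwi, sch, masks, truth


@pytest.fixture(scope="session")
def small_noisy():
    spec = PhantomSpec(snr=30.0, seed=7, **SMALL_KW)
    dwi, sch, masks, truth = generate_phantom(spec)
    return spec, dwi, sch, masks, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
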