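import numpy as np
import pytest

from egan3d.phantoms import PhantomSpec, make_paired_phantom
from egan3d.volume import Volume


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_phantom():
    """One 16^3 phantom pair with its tissue label map (session-cached)."""
    spec = PhantomSpec(extent=16, seed=3)
    return make_paired_phantom(spec)


@pytest.fixture(scope="session")
def clean_phantom():
    """Noise-free, unsmoothed 24^3 phantom: PET is an exact tissue remap."""
    spec = PhantomSpec(extent=24, seed=5, smoothing_fwhm_mm=0.0, noise_sigma=0.0)
    return make_paired_phantom(spec)


@pytest.fixture()
def random_volume(rng):
    def make(shape=(6, 6, 6), lo=0.0, hi=1.0):
        return Volume(rng.uniform(lo, hi, size=shape))

    return make
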