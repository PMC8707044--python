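import numpy as np
import pytest
from hypothesis import settings

# property tests are derandomized; skip the example database entirely
settings.register_profile("no_db", database=None)
settings.load_profile("no_db")

from wheatlai.spectra import SpectraSet
from wheatlai.synthetic import CanopySimConfig, generate_dataset


@pytest.fixture(scope="session")
def clean_dataset() -> SpectraSet:
    """Noise-free 48-plot jointing-stage dataset on the full 1 nm grid."""
    return generate_dataset(CanopySimConfig(noise_sd=0.0, seed=7))


@pytest.fixture(scope="session")
def noisy_dataset() -> SpectraSet:
    """Default-noise (sd = 0.01) 48-plot jointing-stage dataset."""
    return generate_dataset(CanopySimConfig(noise_sd=0.01, seed=7))


@pytest.fixture()
def small_spectra() -> SpectraSet:
    """Tiny deterministic 5-sample, 64-band set for oracle comparisons."""
    rng = np.random.default_rng(42)
    wl = np.arange(400.0, 464.0)
    refl = np.clip(rng.normal(0.3, 0.05, size=(5, wl.size)), 0.0, 1.0)
    lai = rng.uniform(1.0, 4.0, size=5)
    return SpectraSet(wl, refl, lai)
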