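import numpy as np
import pytest

import somspec as ss


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def toy_spectrum(rng):
    """31-band smooth-ish random reflectance well inside (0, 1)."""
    wl = np.arange(500, 531)
    vals = 0.5 + 0.25 * np.sin(wl[None, :] / 7.0) + 0.05 * rng.standard_normal((4, 31))
    vals = np.clip(vals, 0.2, 0.8)
    ids = [f"s{k}" for k in range(4)]
    return ss.SpectrumSet(ids, wl, vals, "R")


@pytest.fixture(scope="session")
def small_soil_data():
    """One modest synthetic data set shared by read-only tests."""
    s, som = ss.generate_soil_spectra(ss.SyntheticConfig(n_samples=60, seed=7))
    return s, som


@pytest.fixture(scope="session")
def small_transforms(small_soil_data):
    s, som = small_soil_data
    return ss.all_transforms(s), som
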