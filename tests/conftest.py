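import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from organellems import fixtures, spectra

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def default_config() -> fixtures.FixtureConfig:
    return fixtures.FixtureConfig(seed=11)


@pytest.fixture(scope="session")
def image_fix(default_config):
    return fixtures.make_image(default_config)


@pytest.fixture(scope="session")
def spectra_fix(default_config):
    """120 spectra: 60 DCV (3 planted subpopulations) + 60 LV."""
    cfg = default_config.with_(n_spectra_per_class=60)
    return cfg, fixtures.make_spectra(cfg)


@pytest.fixture(scope="session")
def peak_matrix(spectra_fix) -> spectra.PeakMatrix:
    """Picked and aligned (uncalibrated) feature matrix of the 120 spectra."""
    _, specs = spectra_fix
    pls = [spectra.pick_peaks(s.mz, s.intensity, s.spectrum_id) for s in specs]
    return spectra.align_bins(pls, gap_ppm=5.0, mz_window=(450.0, 1450.0))


@pytest.fixture(scope="session")
def calibrants() -> pd.DataFrame:
    """The two tall peptide-like peaks planted in every DCV spectrum."""
    return pd.DataFrame({"name": ["calA", "calB"], "mz": [1221.6878, 1396.7225]})


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(7)
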