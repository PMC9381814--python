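import numpy as np
import pytest

from leafchem.preprocessing import savgol_smooth
from leafchem.synthetic_data import (
    AnalytePanelConfig,
    OpticsConfig,
    StudyConfig,
    generate_study,
)


@pytest.fixture(scope="session")
def default_panel() -> AnalytePanelConfig:
    return AnalytePanelConfig.default()


@pytest.fixture(scope="session")
def study_table():
    """Scaled synthetic study: full sample size, 60-band grid.

    The 60-band grid keeps PLS/LOO work affordable in tests; the generator
    and every algorithm are identical to the full 300-band setting.
    """
    return generate_study(StudyConfig(n_bands=60, seed=7))


@pytest.fixture(scope="session")
def smoothed_table(study_table):
    return study_table.with_spectra(savgol_smooth(study_table.spectra()))


@pytest.fixture(scope="session")
def quiet_optics() -> OpticsConfig:
    """Noise-free forward model (for exactness checks)."""
    return OpticsConfig(noise_sd=0.0, multiplicative_sd=0.0)
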