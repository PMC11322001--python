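import numpy as np
import pytest

from cytodroplet import synthetic as syn


@pytest.fixture(scope="session")
def filament_ensemble():
    """Equipartition filament ensemble at the study conditions."""
    truth = syn.FilamentTruth(kappa=0.04, length=6.0, temperature=293.0, frames=500, k_max=4)
    return syn.gen_fluctuating_filament(truth, seed=11)


@pytest.fixture
def disk_mask():
    yy, xx = np.mgrid[0:200, 0:200]
    return (xx - 100.0) ** 2 + (yy - 100.0) ** 2 <= 60.0**2


@pytest.fixture
def ellipse_mask():
    """2:1 ellipse, semi-axes 120 and 60 px."""
    yy, xx = np.mgrid[0:300, 0:300]
    return ((xx - 150.0) / 120.0) ** 2 + ((yy - 150.0) / 60.0) ** 2 <= 1.0
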