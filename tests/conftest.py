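import numpy as np
import pytest

from luquant.physics import get_material, linear_attenuation
from luquant.simulate import default_calibration_truth
from luquant.spectra import LU177_WINDOWS


@pytest.fixture(scope="session")
def windows():
    return LU177_WINDOWS


@pytest.fixture(scope="session")
def truth_megp_tew():
    """Synthetic ground-truth calibration (MEGP, TEW mode): (sens, buildup)."""
    return default_calibration_truth("MEGP", scatter_corrected=True)


@pytest.fixture(scope="session")
def soft_tissue_mu():
    return linear_attenuation(get_material("soft_tissue"))


@pytest.fixture
def rng():
    return np.random.default_rng(20240103)
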