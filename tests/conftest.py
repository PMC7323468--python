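import numpy as np
import pytest

from lumbarqmri import phantom
from lumbarqmri.grids import ImageVolume


@pytest.fixture(scope="session")
def small_config():
    """Reduced-volume phantom (10% muscle volumes): same fat fractions,
    tensors, and level structure as the defaults, but fast to rasterize."""
    return phantom.default_config(
        n_subjects=2, between_subject_cv=0.0, snr=40.0, seed=7, volume_scale=0.1
    )


@pytest.fixture(scope="session")
def small_subject(small_config):
    return phantom.generate_subject(small_config, 0)


@pytest.fixture(scope="session")
def noiseless_config():
    return phantom.default_config(
        n_subjects=1, between_subject_cv=0.0, snr=None, seed=3, volume_scale=0.1
    )


@pytest.fixture(scope="session")
def noiseless_subject(noiseless_config):
    return phantom.generate_subject(noiseless_config, 0)


@pytest.fixture
def unit_volume():
    """1 mm isotropic 8×8×8 volume of zeros at the origin."""
    return ImageVolume(np.zeros((8, 8, 8)), (1.0, 1.0, 1.0))
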