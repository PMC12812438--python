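import numpy as np
import pytest

from fpm.optics import CavitySpec, LaserLine


@pytest.fixture
def cavity() -> CavitySpec:
    """Reference cavity: 50 um channel, R = 0.68, water-like medium."""
    return CavitySpec()


@pytest.fixture
def line() -> LaserLine:
    """Reference laser: 515-519 nm scan, 35 steps, 0.29 nm FWHM."""
    return LaserLine()


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
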