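import numpy as np
import pytest

from spectramct import (
    EnergyBinning,
    SpectralVolume,
    build_phantom,
    default_phantom_config,
)


@pytest.fixture(scope="session")
def binning():
    return EnergyBinning.five_bin_protocol()


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def make_volume(data, binning=None, **kwargs):
    binning = binning or EnergyBinning.five_bin_protocol()
    return SpectralVolume(data=np.asarray(data, dtype=np.float64),
                          binning=binning, **kwargs)


@pytest.fixture
def small_volume(binning, rng):
    """A small random 5-bin volume for plumbing tests."""
    data = rng.normal(0.3, 0.05, size=(6, 5, 4, 5))
    return make_volume(data, binning)


@pytest.fixture(scope="session")
def default_phantom():
    """One default diffuse-iodine phantom scan, shared across read-only tests."""
    return build_phantom(default_phantom_config(seed=7))
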