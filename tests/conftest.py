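import numpy as np
import pytest

from petquant.synthetic_data import (
    AifShape,
    aif_function,
    make_aif,
    make_schedule,
    make_subject,
    make_vessel_phantom,
)


@pytest.fixture(scope="session")
def schedule():
    """The 26-frame, 60-minute acquisition grid."""
    return make_schedule()


@pytest.fixture(scope="session")
def aif_shape():
    return AifShape()


@pytest.fixture(scope="session")
def aif_func(aif_shape):
    return aif_function(aif_shape)


@pytest.fixture(scope="session")
def aif_tac(aif_shape, schedule):
    return make_aif(aif_shape, schedule)


@pytest.fixture(scope="session")
def subject():
    """Noiseless synthetic subject with the default (r=0.25) mixing."""
    return make_subject("pib_pos", seed=1)


@pytest.fixture(scope="session")
def noisy_subject():
    return make_subject("pib_pos", seed=1, noise=0.01)


@pytest.fixture(scope="session")
def phantom():
    """Default 1 mm curved-tube phantom (with intensity noise)."""
    return make_vessel_phantom(seed=0)


@pytest.fixture(scope="session")
def clean_phantom():
    return make_vessel_phantom(seed=0, noise_sd=0.0)
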