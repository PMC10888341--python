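import numpy as np
import pytest

from blendsense import (
    Illuminant,
    OilIdentity,
    default_config,
    generate_calibration_dataset,
    generate_classification_dataset,
)


@pytest.fixture
def cfg():
    return default_config(seed=0)


@pytest.fixture
def noiseless_linear_cfg():
    # affine-in-fraction regime: no noise, count-space linear mixing
    return default_config(seed=0, noise_sd=0.0, nonlinearity=0.0)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def classification_dataset():
    return generate_classification_dataset(default_config(seed=0), Illuminant.WHITE)


@pytest.fixture(scope="session")
def canola_calibration_dataset():
    return generate_calibration_dataset(
        OilIdentity.CANOLA, default_config(seed=0), Illuminant.WHITE
    )
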