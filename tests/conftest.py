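import numpy as np
import pytest

from arousalkit.types import ModelParams
from arousalkit import synthetic_data as sd


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def symmetric_params():
    return ModelParams(beta_pos=0.5, beta_neg=0.5, mu=0.0, sigma=1.0)


@pytest.fixture(scope="session")
def asymmetric_params():
    return ModelParams(beta_pos=0.5, beta_neg=0.2, mu=0.0, sigma=1.0)


@pytest.fixture(scope="session")
def long_symmetric_series(symmetric_params):
    return sd.simulate_arousal_series(symmetric_params, 100_000, seed=7)


@pytest.fixture(scope="session")
def small_recording(asymmetric_params):
    masks = sd.MasksConfig(duration_s=3 * 3600.0)
    return sd.simulate_day_recording(asymmetric_params, masks, seed=42)
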