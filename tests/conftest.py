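import numpy as np
import pytest

from survbma.core import SurvivalDataset


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def five_record_data():
    """Small mixed-censoring fixture with two covariates (plus intercept)."""
    times = np.array([0.5, 1.2, 2.0, 3.3, 0.8])
    events = np.array([1, 0, 1, 0, 1])
    X = np.array(
        [
            [1.0, 0.3, -1.1],
            [1.0, -0.6, 0.4],
            [1.0, 1.2, 0.0],
            [1.0, 0.0, 0.9],
            [1.0, -1.5, -0.2],
        ]
    )
    return SurvivalDataset(times, events, X, ["intercept", "x1", "x2"])


@pytest.fixture
def four_record_data():
    times = np.array([0.4, 1.5, 2.5, 0.9])
    events = np.array([1, 0, 1, 1])
    X = np.array(
        [
            [1.0, 0.5],
            [1.0, -0.8],
            [1.0, 1.1],
            [1.0, 0.0],
        ]
    )
    return SurvivalDataset(times, events, X, ["intercept", "x1"])
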