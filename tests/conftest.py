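import logging

import numpy as np
import pytest

from lagnet.config import InferenceConfig
from lagnet.data_io import TimeSeriesSet

logging.disable(logging.WARNING)


@pytest.fixture
def fast_config() -> InferenceConfig:
    """Config with cheap scaling settings for unit tests."""
    return InferenceConfig(mds_restarts=5, mds_max_iter_factor=200)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260929)


def make_timeseries(times, columns: dict, errors: dict | None = None) -> TimeSeriesSet:
    """Assemble a TimeSeriesSet from per-species columns."""
    species = list(columns)
    values = np.column_stack([np.asarray(columns[s], dtype=float) for s in species])
    err = None
    if errors is not None:
        err = np.column_stack([np.asarray(errors[s], dtype=float) for s in species])
    return TimeSeriesSet(species=species, times=np.asarray(times, float), values=values, errors=err)


@pytest.fixture
def two_decay_series() -> TimeSeriesSet:
    """Noise-free A -> B relaxation sampled densely (closed-form dynamics)."""
    t = np.linspace(0.0, 5.0, 60)
    a = np.exp(-t)
    return make_timeseries(t, {"A": a, "B": 1.0 - a})
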