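import datetime as dt

import numpy as np
import pytest

from mesoflux.config import RunConfig, SimConfig
from mesoflux.simulate import simulate_mesocosm


@pytest.fixture(scope="session")
def short_config() -> SimConfig:
    """A five-week, four-collar campaign: long enough to span all four
    developmental stages and the correction onset, small enough for fast tests."""
    return SimConfig(end_date=dt.date(2006, 12, 10), n_collars=4,
                     chambered_fraction=1.0, rng_seed=0)


@pytest.fixture(scope="session")
def short_sim(short_config):
    return simulate_mesocosm(short_config)


@pytest.fixture(scope="session")
def short_runconfig(short_config) -> RunConfig:
    return RunConfig(sim=short_config)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
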