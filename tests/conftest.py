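import numpy as np
import pytest

from agghg.config import RunConfig, SyntheticConfig
from agghg.pipeline import run_pipeline


@pytest.fixture
def small_config() -> SyntheticConfig:
    """Toy-world config small enough for unit tests."""
    return SyntheticConfig(seed=7, grid_shape=(8, 10), ef_obs_n=400)


@pytest.fixture(scope="session")
def small_run():
    """One reduced-size pipeline run shared across pipeline tests."""
    cfg = RunConfig(
        seed=11,
        synthetic=SyntheticConfig(seed=11, grid_shape=(10, 12)),
        mc_draws=500,
        bootstrap_reps=200,
    )
    return run_pipeline(cfg)


@pytest.fixture(scope="session")
def default_run():
    """The default study-condition run (full toy grid, default draws)."""
    return run_pipeline(RunConfig(seed=0))


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
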