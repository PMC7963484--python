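import numpy as np
import pytest

from thalcort import EventTrainConfig, GridSpec, run_grid


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def _grid(rule, h_pct, n_runs=100, seed=2024):
    return run_grid(
        GridSpec(
            rule=rule,
            n_runs=n_runs,
            master_seed=seed,
            events=EventTrainConfig(h_pct_range=h_pct),
        )
    )


@pytest.fixture(scope="session")
def hebb_grid_80():
    """Non-adaptive Hebbian grid, H participation 80-100% (reduced scale)."""
    return _grid("hebb", (0.8, 1.0))


@pytest.fixture(scope="session")
def hebb_grid_70():
    return _grid("hebb", (0.7, 1.0))


@pytest.fixture(scope="session")
def adaptive_grid_80():
    return _grid("hebb_adaptive", (0.8, 1.0))


@pytest.fixture(scope="session")
def adaptive_grid_70():
    return _grid("hebb_adaptive", (0.7, 1.0))


@pytest.fixture(scope="session")
def bcm_grid_80():
    return _grid("bcm", (0.8, 1.0))
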