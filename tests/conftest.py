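import numpy as np
import pytest

from wmfusion import paradigm_sim as ps


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def desk_config():
    """Default desk-scale configuration (20x20x10 grid, 256 Hz EEG)."""
    return ps.ParadigmConfig()


@pytest.fixture
def tiny_config():
    """Few trials, tiny grid: fast enough for per-operation tests.

    Needs at least 7 trials per load so the six mean-centred band
    modulators per load stay linearly independent.
    """
    return ps.ParadigmConfig(
        trials_per_load=8,
        n_baseline_blocks=2,
        n_scans=125,
        grid_shape=(6, 6, 4),
    )


@pytest.fixture
def desk_schedule(desk_config, rng):
    return ps.make_trial_schedule(desk_config, rng)


@pytest.fixture
def desk_truth(desk_config):
    return ps.default_truth(desk_config, seed=0)
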