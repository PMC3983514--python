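import numpy as np
import pytest

import cardiobuckle as cb


@pytest.fixture
def config():
    return cb.default_config()


@pytest.fixture
def coarse_config():
    """Coarse, short configuration for fast growth-loop tests."""
    cfg = cb.ensemble_config()
    cfg.growth.final_fed_length = 200.0
    return cfg


@pytest.fixture(scope="session")
def exp1_trajectory():
    """The confined full-growth run shared by the acceptance checks.

    One run at the apparatus defaults (1 mm feed steps, ~4 mm node
    spacing), carried from the initial 136 mm to the final 350 mm.
    """
    cfg = cb.default_config()
    return cb.run_growth(cfg)


def rng(seed=0):
    return np.random.default_rng(seed)
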