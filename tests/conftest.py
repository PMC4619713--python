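import numpy as np
import pytest

from benthoscape.seascape import SeascapeConfig, generate_seascape

#: backscatter parameters with essentially non-overlapping class distributions,
#: used where a test needs acoustically well-separated classes
SEPARATED_BS = {
    "hard": {"mean": -21.0, "sd": 0.5},
    "mixed": {"mean": -25.0, "sd": 0.4},
    "soft": {"mean": -28.0, "sd": 0.4},
}


@pytest.fixture(scope="session")
def small_truth():
    """A modest default-parameter seascape shared across read-only tests."""
    cfg = SeascapeConfig(grid_nx=120, grid_ny=120, seed=31)
    return generate_seascape(cfg)


@pytest.fixture(scope="session")
def separated_truth():
    """A seascape with well-separated class parameters and calm bathymetry."""
    cfg = SeascapeConfig(
        grid_nx=160,
        grid_ny=160,
        seed=13,
        backscatter_params=SEPARATED_BS,
        depth_noise_sd=0.3,
    )
    return generate_seascape(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
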