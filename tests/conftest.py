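import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # makes `oracles` importable

from steptime.mocap_io import Config
from steptime.simulate import TrajectoryParams, generate_trial


@pytest.fixture(scope="session")
def cfg() -> Config:
    return Config()


@pytest.fixture(scope="session")
def clean_trial():
    """A noiseless default trial with its ground truth (expensive; share it)."""
    params = TrajectoryParams(seed=11, noise_sd_mm=0.0)
    return generate_trial([1, 6, 5, 2, 3, 4], params)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
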