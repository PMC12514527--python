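import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # makes `oracles` importable

from engramnet import CohortConfig, generate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """A fast 2x4-animal cohort with the planted hub effect."""
    cfg = CohortConfig(seed=42, n_per_group=4, samples_per_bin=250)
    animals, behavior = generate_cohort(cfg)
    return cfg, animals, behavior


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
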