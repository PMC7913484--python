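import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))

from honeynir import SpectraSet, SyntheticConfig, generate_dataset


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture(scope="session")
def default_dataset():
    """Default synthetic dataset, seed 7, shared across tests."""
    return generate_dataset(SyntheticConfig(seed=7))


@pytest.fixture
def small_spectra(rng):
    wl = np.linspace(908.0, 1676.0, 40)
    values = rng.normal(size=(6, 40)).cumsum(axis=1) / 10 + 1.0
    return SpectraSet([f"s{i}" for i in range(6)], wl, values)


#: representative treatment grid covering every scatter option (kept small
#: so full-pipeline tests stay fast)
SMALL_GRID = ("None 0,0,1,1", "None 1,4,4,1", "SNV 1,4,4,1", "MSC 1,4,4,1",
              "Detrend only 1,4,4,1", "SNV-DT 1,4,4,1")
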