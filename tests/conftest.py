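import numpy as np
import pytest

from strsift.complexity import ThresholdTable
from strsift.simulate import SimConfig


@pytest.fixture(scope="session")
def toy_table():
    """Fixed threshold table for unit tests (not calibrated)."""
    return ThresholdTable(entries={50: 0.50, 150: 0.40}, provenance="builtin")


@pytest.fixture(scope="session")
def uniform_config():
    return SimConfig(background="uniform", read_length=150, seed=1234)


@pytest.fixture()
def rng():
    return np.random.default_rng(20260928)
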