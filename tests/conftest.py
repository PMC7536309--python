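import numpy as np
import pytest

from socovsel import SyntheticConfig, generate, generate_assayed


@pytest.fixture(scope="session")
def default_dataset():
    """Default synthetic cohort: 21 samples, retained blocks 32/23/4."""
    ds, truth = generate(SyntheticConfig(seed=7))
    return ds, truth


@pytest.fixture(scope="session")
def assayed_dataset():
    """Full assayed panel (37/31/7) with the 16 study analytes censored."""
    ds, truth = generate_assayed(SyntheticConfig(seed=7))
    return ds, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
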