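import numpy as np
import pytest

from snomchemo import AtrSimConfig, ClassEffectTable, SnomSimConfig, generate_atr_dataset


@pytest.fixture(scope="session")
def default_atr_dataset():
    """The default 5-class, 10-per-class synthetic ATR dataset (fixed seed)."""
    return generate_atr_dataset(AtrSimConfig(), seed=11)


@pytest.fixture
def noise_free_snom_config():
    return SnomSimConfig(noise_sd=0.0, line_offset_sd=0.0)


@pytest.fixture
def default_effects():
    return ClassEffectTable()


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
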