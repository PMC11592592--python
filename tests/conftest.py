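import numpy as np
import pytest

from mirdescribe.simulate import GeneratorConfig, generate_dataset


@pytest.fixture(scope="session")
def small_dataset():
    """300 mixed hairpin/decoy records, fixed seed."""
    return generate_dataset(GeneratorConfig(n_samples=300, seed=42))


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
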