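import numpy as np
import pytest

from srtsim import build_corpus


@pytest.fixture(scope="session")
def corpus():
    """Default synthetic corpus, shared across the suite (read-only)."""
    return build_corpus(master_seed=1)


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
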