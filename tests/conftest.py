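import numpy as np
import pytest

from designanalysis import DesignConfig


@pytest.fixture
def fast_config() -> DesignConfig:
    """Reduced-replicate profile: Monte-Carlo SE ~2x the reference run."""
    return DesignConfig(n_sims=20_000, seed=7)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)

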