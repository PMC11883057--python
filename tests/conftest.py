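import numpy as np
import pytest

from mcesim import SimParams, validate_params


@pytest.fixture
def make_params():
    """Factory for validated parameter sets with test-friendly defaults."""

    def _make(**overrides) -> SimParams:
        base = dict(n_adults=100, q0=0.05, n_generations=50, n_replicates=10, base_seed=0)
        base.update(overrides)
        return validate_params(base)

    return _make


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
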