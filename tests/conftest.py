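import numpy as np
import pytest

from clonerisk.simulate import SimConfig, make_programs


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def small_config():
    """Small but non-trivial count model for fast unit tests."""
    return SimConfig(n_genes=300, n_subclones=3, n_markers_per_subclone=30,
                     dispersion=2.0, seed=7)


@pytest.fixture
def small_programs(small_config):
    return make_programs(small_config)
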