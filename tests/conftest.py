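import numpy as np
import pytest

from nucleoscreen.synthetic import SimConfig


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def small_config():
    """A small screen: 30 mimics, two planted hits, modest well occupancy."""
    return SimConfig(
        seed=7,
        n_mimics=30,
        cells_per_well_mean=300,
        effect_sizes={
            "mimic-0001": ("one-nucleolus", 0.8),
            "mimic-0002": ("five-plus", 0.8),
        },
    )
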