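import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("ci", derandomize=True, max_examples=50,
                          deadline=None)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(20160)


@pytest.fixture
def four_row_scores():
    """y=(0,0,1,1), scores=(0.1,0.4,0.35,0.8): 3 concordant pairs of 4."""
    return np.array([0, 0, 1, 1]), np.array([0.1, 0.4, 0.35, 0.8])
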