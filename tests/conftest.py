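import numpy as np
import pytest

from linksom.som_core import SOMConfig, SOMGrid
from linksom.synthetic import make_cluster_matrix, make_planted_block_grid


def make_planted_grid(rows, cols, b, **kwargs):
    return make_planted_block_grid(rows, cols, b, **kwargs)


@pytest.fixture
def cluster_matrix():
    return make_cluster_matrix(seed=7)


@pytest.fixture
def small_grid():
    rng = np.random.default_rng(3)
    return SOMGrid(5, 6, rng.uniform(0, 1, (30, 8)),
                   SOMConfig(rows=5, cols=6), fit_error=0.0)
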