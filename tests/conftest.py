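import numpy as np
import pytest
from hypothesis import settings

from ictfce import StatMatrix, TFCEParams

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")
from ictfce.synth import SynthMatrixConfig, synth_stat_matrix


@pytest.fixture
def k3_matrix():
    """Triangle graph with edge statistics {3, 2, 1}."""
    return StatMatrix(np.array([[0.0, 3.0, 2.0], [3.0, 0.0, 1.0], [2.0, 1.0, 0.0]]))


@pytest.fixture
def unit_params():
    """E=1, H=1, dh=1: every hand-derived example uses these."""
    return TFCEParams(extent_exponent=1.0, height_exponent=1.0, dh=1.0)


def smoothed_matrix(n, seed, sigma=None):
    return synth_stat_matrix(SynthMatrixConfig(n_rois=n, filter_sigma=sigma, seed=seed))


def random_sparse_stats(n, seed, density=0.5, scale=3.0):
    """Random symmetric matrix where only some edges carry positive mass."""
    rng = np.random.default_rng(seed)
    a = np.where(rng.random((n, n)) < density, rng.uniform(0, scale, (n, n)), -1.0)
    a = np.triu(a, k=1)
    return StatMatrix(a + a.T)
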