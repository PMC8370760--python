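import numpy as np
import pytest

from mvreact.synthetic import SimConfig, simulate_experiment


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture(scope="session")
def small_cfg():
    return SimConfig(n_subjects=3, n_images=18, images_per_run=6,
                     n_runs_encode=3, channels_per_layer=4,
                     n_vertices_per_roi=12, n_movie_samples=20, seed=11)


@pytest.fixture(scope="session")
def small_exp(small_cfg):
    """One small simulated experiment shared across read-only tests."""
    return simulate_experiment(small_cfg, include_movie=True)
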