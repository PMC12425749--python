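"""Shared fixtures: small deterministic systems and datasets."""

import numpy as np
import pytest

import stgf
from stgf.config import (
    GeometryConfig,
    NoiseConfig,
    PhantomConfig,
    ReconConfig,
    RunConfig,
    StoppingConfig,
)


@pytest.fixture(scope="session")
def small_system():
    """16x16 image, 6 angles, 22 radial bins."""
    return stgf.build_system_matrix(16, 6, 22)


def tiny_config(side=31, realizations=2, mlem_iters=8, t_max=3) -> RunConfig:
    cfg = RunConfig.demo()
    cfg.phantom = PhantomConfig(side=side)
    cfg.geometry = GeometryConfig(n_angles=side, n_radial=side)
    n = cfg.noise
    cfg.noise = NoiseConfig(n.background_fraction, n.total_counts, realizations)
    cfg.recon = ReconConfig(n_iterations=mlem_iters, inner_iterations=mlem_iters)
    s = cfg.stopping
    cfg.stopping = StoppingConfig(s.epsilon, s.w1, s.w2, t_max)
    return cfg


@pytest.fixture(scope="session")
def tiny_dataset():
    """31x31 phantom, 2 noisy realizations; fast enough for engine tests."""
    return stgf.simulate_dataset(tiny_config(), seed=7)


@pytest.fixture(scope="session")
def tiny_system(tiny_dataset):
    return tiny_dataset.system()
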