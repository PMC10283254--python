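import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from scsnf.io import OmicsBlock
from scsnf.simulate import SimulationConfig, simulate_study

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_study():
    """A compact planted-structure study reused by several suites."""
    cfg = SimulationConfig(
        n_subjects=80,
        n_features={"protein": 120, "mirna": 80, "torna": 150},
        seed=11,
    )
    return simulate_study(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)


def make_block(values, modality="protein", subjects=None, features=None):
    values = np.asarray(values, dtype=float)
    n, f = values.shape
    subjects = subjects or [f"S{i:03d}" for i in range(n)]
    features = features or [f"{modality}_f{j:03d}" for j in range(f)]
    return OmicsBlock(modality, subjects, features, values)


@pytest.fixture()
def block_factory():
    return make_block


def planted_affinity(sizes, within=1.0, between=0.0, noise=0.0, seed=0):
    """Block-diagonal affinity with optional symmetric uniform noise."""
    rng = np.random.default_rng(seed)
    n = sum(sizes)
    W = np.full((n, n), between, dtype=float)
    start = 0
    for s in sizes:
        W[start:start + s, start:start + s] = within
        start += s
    if noise:
        jitter = rng.uniform(0, noise, size=(n, n))
        W = W + (jitter + jitter.T) / 2
    np.fill_diagonal(W, within)
    return W


@pytest.fixture()
def affinity_factory():
    return planted_affinity
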