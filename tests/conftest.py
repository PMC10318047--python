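import numpy as np
import pytest

from ofmap.session import SessionLayout
from ofmap.synthetic import BehaviorGenConfig, CellGenConfig, generate_session


@pytest.fixture(scope="session")
def layout():
    return SessionLayout()


@pytest.fixture(scope="session")
def default_session():
    """One full-size synthetic session reused by read-only tests."""
    return generate_session(seed=7)


@pytest.fixture(scope="session")
def small_cells_session():
    """Full-length session with a small cell population (fast imaging tests)."""
    return generate_session(cellcfg=CellGenConfig(n_cells=30), seed=11)


@pytest.fixture(scope="session")
def behavior_cohort():
    """Three behavior-only sessions (no cells) for mapping tests."""
    cellcfg = CellGenConfig(n_cells=0)
    return [generate_session(cellcfg=cellcfg, seed=100 + i) for i in range(3)]


@pytest.fixture
def rng():
    return np.random.default_rng(0)


def make_separated_modes(n_per_mode=50, n_modes=3, dim=40, sep=30.0, seed=0):
    """Well-separated Gaussian blobs in feature space with mode labels."""
    r = np.random.default_rng(seed)
    centers = r.normal(0, sep, size=(n_modes, dim))
    X = np.vstack([c + r.normal(0, 1.0, size=(n_per_mode, dim)) for c in centers])
    labels = np.repeat(np.arange(n_modes), n_per_mode)
    return X, labels
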