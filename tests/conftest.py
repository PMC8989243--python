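import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # expose tests/oracles.py

from mfgreg.basis import FunctionalDataset, build_basis


def make_dataset(n=30, p=3, m=4, seed=0, order=4, noise=0.1, n_active=None,
                 kind="bspline"):
    """Random toy dataset directly in coordinates (tag B)."""
    rng = np.random.default_rng(seed)
    basis = build_basis(kind, m, (0.0, 1.0), order=order)
    bases = [basis] * p
    coords = rng.standard_normal((p * m, n))
    beta = np.zeros(p * m)
    k = p if n_active is None else n_active
    beta[: k * m] = rng.standard_normal(k * m)
    G = np.kron(np.eye(p), basis.gram)
    y = coords.T @ G @ beta + noise * rng.standard_normal(n)
    return FunctionalDataset(bases=bases, coords=coords, response=y)


@pytest.fixture
def toy_dataset():
    return make_dataset()


@pytest.fixture(scope="session")
def cubic_basis():
    return build_basis("bspline", 6, (0.0, 1.0), order=4)


@pytest.fixture(scope="session")
def fourier_basis():
    return build_basis("fourier", 5, (0.0, 1.0))
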