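import numpy as np
import pytest

from fstratio import QMatrix


@pytest.fixture
def simple_q() -> QMatrix:
    """The 2x2 maximizing configuration for M = 0.75: F_ST = F_STmax = 1/3."""
    return QMatrix(np.array([[1.0, 0.0], [0.5, 0.5]]))


@pytest.fixture
def identity_q() -> QMatrix:
    return QMatrix(np.eye(2))


def random_qmatrix(rng: np.random.Generator, i_count=None, k_count=None) -> QMatrix:
    """A random valid, polymorphic Q matrix: Dirichlet rows with random
    concentration.  Redraws the rare matrix whose pooled heterozygosity is
    at float-noise level (statistics there are undefined or meaningless)."""
    i_count = i_count or int(rng.integers(2, 12))
    k_count = k_count or int(rng.integers(2, 6))
    while True:
        alpha = float(rng.uniform(0.2, 5.0))
        lam = rng.dirichlet(np.ones(k_count))
        rows = rng.gamma(np.maximum(alpha * lam, 0.05), size=(i_count, k_count))
        rows = rows / rows.sum(axis=1, keepdims=True)
        means = rows.mean(axis=0)
        if 1.0 - np.sum(means**2) > 1e-9 and means.max() < 1 - 1e-6:
            return QMatrix(rows)
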