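import numpy as np
import pytest

from segtraj import ConnectivityMatrix, Partition


def make_matrix(upper: dict[tuple[int, int], float], n: int) -> ConnectivityMatrix:
    """Build a ConnectivityMatrix from sparse upper-triangle entries."""
    v = np.zeros((n, n))
    for (i, j), z in upper.items():
        v[i, j] = v[j, i] = z
    return ConnectivityMatrix(values=v)


def make_partition(labels, density: float = 0.07) -> Partition:
    return Partition(
        labels=np.asarray(labels, dtype=int),
        density=density,
        quality=0.0,
        method="fixture",
        seed=0,
    )


def random_symmetric(n: int, rng: np.random.Generator, scale: float = 1.0) -> ConnectivityMatrix:
    v = rng.normal(scale=scale, size=(n, n))
    v = (v + v.T) / 2
    np.fill_diagonal(v, 0.0)
    return ConnectivityMatrix(values=v)


@pytest.fixture
def rng():
    return np.random.default_rng(20261002)
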