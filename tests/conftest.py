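import numpy as np
import pytest

from biclustbench import Bicluster, Biclustering


def random_bicluster(rng, n, p, allow_empty=True):
    """A random bicluster on an n x p grid (possibly empty)."""
    lo = 0 if allow_empty else 1
    ns = rng.integers(lo, n + 1)
    ng = rng.integers(lo, p + 1)
    samples = rng.choice(n, size=ns, replace=False)
    genes = rng.choice(p, size=ng, replace=False)
    return Bicluster(samples, genes)


def random_biclustering(rng, n, p, max_k, allow_empty=True):
    k = rng.integers(0, max_k + 1)
    return Biclustering(
        [random_bicluster(rng, n, p, allow_empty) for _ in range(k)], n, p
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20210506)


@pytest.fixture
def small_grid_pair(rng):
    """Two random biclusterings on a common small grid."""
    return (
        random_biclustering(rng, 6, 7, 4),
        random_biclustering(rng, 6, 7, 4),
    )
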