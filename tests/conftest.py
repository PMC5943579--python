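import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from commsig import Network, Partition

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def barbell():
    """Two triangles {0,1,2}, {3,4,5} joined by the edge 2-3."""
    net = Network.from_edges([(0, 1), (1, 2), (0, 2), (3, 4), (4, 5), (3, 5), (2, 3)])
    part = Partition([1, 1, 1, 2, 2, 2])
    return net, part


@pytest.fixture
def two_triangles():
    net = Network.from_edges([(0, 1), (1, 2), (0, 2), (3, 4), (4, 5), (3, 5)])
    part = Partition([1, 1, 1, 2, 2, 2])
    return net, part


def random_graph(rng: np.random.Generator, n: int, p: float = 0.4) -> Network:
    """G(n, p) with at least one edge (resampled if empty)."""
    while True:
        iu, ju = np.triu_indices(n, k=1)
        keep = rng.random(iu.size) < p
        if keep.any():
            return Network.from_index_edges(np.column_stack([iu[keep], ju[keep]]), n)


def random_partition(rng: np.random.Generator, n: int, C: int) -> Partition:
    """Random labeling with at most C communities (relabeled contiguously)."""
    return Partition(rng.integers(0, C, size=n))
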