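"""Per-community quality functions q_c and size measures s_c.

All four quality functions are written so that larger is better, which lets a
single maximizer drive community detection for any of them:

* ``mod`` — modularity contribution of one community,
  q_c = (1/2M) sum_{i,j in c} (A_ij - d_i d_j / 2M); summed over communities
  this is exactly Newman modularity.
* ``int`` — internal average degree, q_c = (1/n_c) sum_{i,j in c} A_ij
  (twice the intra-edge count over the node count).
* ``exp`` — minus the expansion, q_c = -cut_c / n_c.
* ``cnd`` — minus the conductance, q_c = -cut_c / vol_c.

Intra sums run over ordered pairs (each undirected intra-edge counts twice);
cut edges are counted once.  Scores are always recomputed from the integer
edge counts, never from cached increments.
"""

from __future__ import annotations

import warnings

import numpy as np

from .graph_core import Network, Partition

__all__ = [
    "OBJECTIVES",
    "community_aggregates",
    "q_from_aggregates",
    "community_scores",
    "q_mod",
    "q_int",
    "q_exp",
    "q_cnd",
    "size_measure",
    "get_quality",
]

OBJECTIVES = ("mod", "int", "exp", "cnd")
SIZE_KINDS = ("nodes", "volume")


def community_aggregates(network: Network, partition: Partition):
    """Return per-community (m_c, n_c, vol_c) as integer arrays of length C.

    m_c is the number of intra-community edges (unordered); the cut size is
    vol_c - 2 m_c.
    """
    if partition.labels.size != network.N:
        raise ValueError("partition does not cover the network")
    mem = partition.membership
    C = partition.C
    n = np.bincount(mem, minlength=C).astype(np.int64)
    vol = np.bincount(mem, weights=network.degrees, minlength=C).astype(np.int64)
    if network.M:
        lu = mem[network.edges[:, 0]]
        lv = mem[network.edges[:, 1]]
        intra = lu == lv
        m = np.bincount(lu[intra], minlength=C).astype(np.int64)
    else:
        m = np.zeros(C, dtype=np.int64)
    return m, n, vol


def q_from_aggregates(m, n, vol, objective: str, M: int) -> np.ndarray:
    """Vectorized quality from integer aggregates; empty communities score 0."""
    m = np.asarray(m, dtype=np.float64)
    n = np.asarray(n, dtype=np.float64)
    vol = np.asarray(vol, dtype=np.float64)
    if objective == "mod":
        if M == 0:
            raise ValueError("modularity undefined on an empty graph (M = 0)")
        two_m = 2.0 * M
        return (2.0 * m - vol * vol / two_m) / two_m
    cut = vol - 2.0 * m
    with np.errstate(divide="ignore", invalid="ignore"):
        if objective == "int":
            return np.where(n > 0, 2.0 * m / np.where(n > 0, n, 1), 0.0)
        if objective == "exp":
            return np.where(n > 0, -cut / np.where(n > 0, n, 1), 0.0)
        if objective == "cnd":
            return np.where(vol > 0, -cut / np.where(vol > 0, vol, 1), 0.0)
    raise ValueError(f"unknown objective {objective!r}")


def community_scores(
    network: Network, partition: Partition, objective: str, size_kind: str = "nodes"
) -> tuple[np.ndarray, np.ndarray]:
    """(q_c, s_c) for every community c = 1..C of the partition."""
    m, n, vol = community_aggregates(network, partition)
    q = q_from_aggregates(m, n, vol, objective, network.M)
    if size_kind == "nodes":
        s = n.astype(np.float64)
    elif size_kind == "volume":
        s = vol.astype(np.float64)
    else:
        raise ValueError(f"unknown size measure {size_kind!r}")
    return q, s


def _single(network, partition, c, objective):
    if not 1 <= c <= partition.C:
        raise ValueError(f"community id {c} out of range 1..{partition.C}")
    m, n, vol = community_aggregates(network, partition)
    if objective == "cnd" and vol[c - 1] == 0:
        warnings.warn(f"community {c} has volume 0; conductance defined as 0")
        return 0.0
    return float(q_from_aggregates(m, n, vol, objective, network.M)[c - 1])


def q_mod(network: Network, partition: Partition, c: int) -> float:
    """Modularity contribution of community c (sums to Newman modularity)."""
    return _single(network, partition, c, "mod")


def q_int(network: Network, partition: Partition, c: int) -> float:
    """Internal average degree of community c."""
    return _single(network, partition, c, "int")


def q_exp(network: Network, partition: Partition, c: int) -> float:
    """Minus the expansion (cut edges per member node) of community c."""
    return _single(network, partition, c, "exp")


def q_cnd(network: Network, partition: Partition, c: int) -> float:
    """Minus the conductance (cut edges over volume) of community c."""
    return _single(network, partition, c, "cnd")


def size_measure(network: Network, partition: Partition, c: int, kind: str = "nodes") -> float:
    """Community size s_c: node count (``nodes``) or degree sum (``volume``)."""
    if not 1 <= c <= partition.C:
        raise ValueError(f"community id {c} out of range 1..{partition.C}")
    if kind == "nodes":
        return float(partition.sizes()[c - 1])
    if kind == "volume":
        return float(partition.volumes(network)[c - 1])
    raise ValueError(f"unknown size measure {kind!r}")


def get_quality(objective: str):
    """The per-community quality function for a detection objective name."""
    try:
        return {"mod": q_mod, "int": q_int, "exp": q_exp, "cnd": q_cnd}[objective]
    except KeyError:
        raise ValueError(f"unknown objective {objective!r}") from None
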