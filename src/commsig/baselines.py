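"""Baseline significance tests for individual communities.

* S-test: a community is significant if it has more intra-community edges
  than the best node subset of the same size found in degree-preserving
  randomizations.  The per-size extremal subsets are found with a greedy
  grow-and-swap local search (KL-style), restarted several times; within one
  randomized network the maxima are non-decreasing in the subset size by
  construction (each search is also seeded with the grown best subset of the
  previous size).  p = (1 + #{randomized maxima >= observed}) / (R + 1).

* L-test criterion: the deterministic node-level rule — a community is
  significant iff every member node has more neighbors inside the community
  than expected under the configuration model, taken here as
  d_i (vol_c - d_i) / 2M (the node's stubs cannot attach to themselves).

Both use the same Sidak-corrected level alpha = 1 - (1 - alpha')^(1/C) as the
(q, s)-test.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import sparse

from .graph_core import Network, Partition
from .null_model import RandomizationConfig, child_seed, randomize
from .quality import community_aggregates
from .qstest import sidak_alpha

__all__ = ["BaselineResult", "s_test", "l_test_criterion", "best_subset_intra_counts"]

logger = logging.getLogger(__name__)


@dataclass
class BaselineResult:
    test_name: str
    community: np.ndarray
    statistic: np.ndarray
    significant: np.ndarray
    alpha: float
    alpha_prime: float
    C: int
    p_value: np.ndarray | None = None
    extra: dict = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "community_id": self.community,
                "test": self.test_name,
                "statistic": self.statistic,
                "alpha": self.alpha,
                "significant": self.significant,
            }
        )
        if self.p_value is not None:
            df.insert(3, "p_value", self.p_value)
        return df


def _swap_refine(A: sparse.csr_matrix, members: np.ndarray, indeg: np.ndarray, max_sweeps: int):
    """Hill-climb on single (member out, non-member in) swaps maximizing intra edges.

    ``indeg`` is the number of neighbors each node has inside the current
    subset; it is updated in place.  Returns the refined member mask.
    """
    N = A.shape[0]
    inside = np.zeros(N, dtype=bool)
    inside[members] = True
    for _ in range(max_sweeps):
        ins = np.flatnonzero(inside)
        outs = np.flatnonzero(~inside)
        if outs.size == 0:
            break
        u = ins[np.argmin(indeg[ins])]
        v = outs[np.argmax(indeg[outs])]
        # A[u, v] term: swapping in v after removing u
        row = A.indices[A.indptr[u] : A.indptr[u + 1]]
        auv = 1 if np.searchsorted(row, v) < row.size and row[np.searchsorted(row, v)] == v else 0
        gain = indeg[v] - indeg[u] - auv
        if gain <= 0:
            break
        inside[u] = False
        inside[v] = True
        nbr_u = A.indices[A.indptr[u] : A.indptr[u + 1]]
        nbr_v = A.indices[A.indptr[v] : A.indptr[v + 1]]
        indeg[nbr_u] -= 1
        indeg[nbr_v] += 1
    return inside


def _grow(A: sparse.csr_matrix, inside: np.ndarray, indeg: np.ndarray, target: int, rng):
    """Greedily add highest-indeg outside nodes until the subset has ``target`` nodes."""
    count = int(inside.sum())
    while count < target:
        cand = np.flatnonzero(~inside)
        best = cand[np.argmax(indeg[cand])]
        if indeg[best] == 0:  # tie among disconnected nodes: pick randomly
            best = rng.choice(cand)
        inside[best] = True
        nbr = A.indices[A.indptr[best] : A.indptr[best + 1]]
        indeg[nbr] += 1
        count += 1
    return inside


def _intra_count(A: sparse.csr_matrix, inside: np.ndarray) -> int:
    x = inside.astype(np.int64)
    return int(x @ (A @ x)) // 2


def best_subset_intra_counts(
    network: Network,
    sizes: list[int],
    rng: np.random.Generator,
    restarts: int = 5,
    max_sweeps: int = 200,
) -> dict[int, int]:
    """Best-found intra-edge count of an exactly-n-node subset, for each n.

    Local search: greedy growth from a random seed node followed by swap
    refinement, with ``restarts`` independent starts per size; sizes are
    processed in increasing order and each size also starts from the grown
    best subset of the previous size, which makes the returned maxima
    non-decreasing in n.
    """
    A = network.adjacency()
    N = network.N
    out: dict[int, int] = {}
    prev_best_mask = None
    for n in sorted(set(sizes)):
        if n > N:
            raise ValueError(f"subset size {n} exceeds N={N}")
        starts = []
        if prev_best_mask is not None:
            starts.append(prev_best_mask.copy())
        for _ in range(restarts):
            mask = np.zeros(N, dtype=bool)
            mask[rng.integers(N)] = True
            starts.append(mask)
        best_val, best_mask = -1, None
        for mask in starts:
            indeg = np.asarray(A @ mask.astype(np.int64)).ravel()
            mask = _grow(A, mask, indeg, n, rng)
            mask = _swap_refine(A, np.flatnonzero(mask), indeg, max_sweeps)
            val = _intra_count(A, mask)
            if val > best_val:
                best_val, best_mask = val, mask
        out[n] = best_val
        prev_best_mask = best_mask
    return out


def s_test(
    network: Network,
    partition: Partition,
    R: int = 500,
    seed: int | None = None,
    alpha_prime: float = 0.05,
    variant: str = "chung_lu",
    restarts: int = 5,
) -> BaselineResult:
    """Extremal intra-edge-count test at fixed node count.

    For each distinct community size n, the strongest n-node subset is sought
    in each of R randomized networks; community c is significant iff the
    fraction of randomized maxima reaching its own intra-edge count is at
    most the Sidak-corrected alpha.
    """
    if R < 1:
        raise ValueError("R must be >= 1")
    m_c, n_c, _ = community_aggregates(network, partition)
    distinct = sorted(set(int(x) for x in n_c))
    maxima = {n: [] for n in distinct}
    for r in range(R):
        ss = child_seed(seed, r)
        rng = np.random.default_rng(ss)
        rand = randomize(network, RandomizationConfig(variant=variant), rng=rng)
        if rand.M == 0:
            continue
        best = best_subset_intra_counts(rand, distinct, rng, restarts=restarts)
        for n in distinct:
            maxima[n].append(best[n])
    logger.debug("s_test randomized maxima: %s", {n: max(v) for n, v in maxima.items() if v})
    R_eff = len(next(iter(maxima.values()))) if distinct else 0
    alpha = sidak_alpha(alpha_prime, partition.C)
    p = np.empty(partition.C)
    for c in range(partition.C):
        vals = np.asarray(maxima[int(n_c[c])])
        p[c] = (1.0 + int((vals >= m_c[c]).sum())) / (R_eff + 1.0)
    return BaselineResult(
        test_name="s_test",
        community=np.arange(1, partition.C + 1),
        statistic=m_c.astype(np.float64),
        significant=p <= alpha,
        alpha=alpha,
        alpha_prime=alpha_prime,
        C=partition.C,
        p_value=p,
        extra={"maxima": maxima, "R": R_eff},
    )


def l_test_criterion(
    network: Network, partition: Partition, alpha_prime: float = 0.05
) -> BaselineResult:
    """Node-level criterion: every member's internal degree must exceed its
    configuration-model expectation d_i (vol_c - d_i) / 2M.

    The statistic reported per community is the minimum margin
    min_i (k_i^int - expectation); significant iff it is positive.
    """
    if network.M < 1:
        raise ValueError("the criterion needs at least one edge (M >= 1)")
    mem = partition.membership
    d = network.degrees.astype(np.float64)
    vol = partition.volumes(network).astype(np.float64)
    # internal degree of each node
    k_int = np.zeros(network.N)
    u, v = network.edges[:, 0], network.edges[:, 1]
    intra = mem[u] == mem[v]
    np.add.at(k_int, u[intra], 1.0)
    np.add.at(k_int, v[intra], 1.0)
    expected = d * (vol[mem] - d) / (2.0 * network.M)
    margin = k_int - expected
    stat = np.array([margin[mem == c].min() for c in range(partition.C)])
    alpha = sidak_alpha(alpha_prime, partition.C)
    return BaselineResult(
        test_name="l_test",
        community=np.arange(1, partition.C + 1),
        statistic=stat,
        significant=stat > 0,
        alpha=alpha,
        alpha_prime=alpha_prime,
        C=partition.C,
    )
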