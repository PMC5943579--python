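"""Degree-based randomization: the configuration-model null ensemble.

Two variants of "random networks preserving the (expected) degree of each
node" are offered:

* ``chung_lu`` (default): each pair (i, j), i < j, is connected independently
  with probability min(1, d_i d_j / 2M), preserving expected degrees.
* ``stub_matching``: degree stubs are paired uniformly at random; self-loops
  and multi-edges are discarded (so total degree can only shrink).

Randomized networks are not forced to be connected — the null ensemble relies
on them often containing many components.  Seeding is counter-based: network
r of a run with base seed s is generated from ``SeedSequence(s, spawn_key=(r,))``,
so the ensemble is reproducible for any worker count and any scheduling.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Callable

import numpy as np
from joblib import Parallel, delayed

from .graph_core import Network, Partition

__all__ = [
    "RandomizationConfig",
    "randomize",
    "child_seed",
    "sample_null_pairs",
    "sample_null_ensemble",
]

logger = logging.getLogger(__name__)

VARIANTS = ("chung_lu", "stub_matching")


@dataclass
class RandomizationConfig:
    variant: str = "chung_lu"
    seed: int | None = None
    R: int = 500

    def __post_init__(self):
        if self.variant not in VARIANTS:
            raise ValueError(f"unknown randomization variant {self.variant!r}")
        if self.R < 1:
            raise ValueError("R must be >= 1")


def child_seed(base_seed: int | None, index: int) -> np.random.SeedSequence:
    """Counter-based per-network seed, independent of worker scheduling."""
    if base_seed is None:
        base_seed = np.random.SeedSequence().entropy
    return np.random.SeedSequence(base_seed, spawn_key=(index,))


def _chung_lu(network: Network, rng: np.random.Generator) -> Network:
    d = network.degrees.astype(np.float64)
    N = network.N
    two_m = 2.0 * network.M
    iu, ju = np.triu_indices(N, k=1)
    p = np.minimum(1.0, d[iu] * d[ju] / two_m)
    keep = rng.random(p.size) < p
    edges = np.column_stack([iu[keep], ju[keep]])
    return Network.from_index_edges(edges, N)


def _stub_matching(network: Network, rng: np.random.Generator) -> Network:
    stubs = np.repeat(np.arange(network.N), network.degrees)
    rng.shuffle(stubs)
    pairs = stubs.reshape(-1, 2)
    return Network.from_index_edges(pairs, network.N)


def randomize(network: Network, config: RandomizationConfig | None = None, *, rng=None) -> Network:
    """Draw one degree-preserving randomization of ``network`` (simple, undirected)."""
    if network.M < 1:
        raise ValueError("cannot randomize a graph with no edges")
    if config is None:
        config = RandomizationConfig()
    if rng is None:
        rng = np.random.default_rng(config.seed)
    if config.variant == "chung_lu":
        return _chung_lu(network, rng)
    return _stub_matching(network, rng)


def _one_network_samples(network, detector, quality_fn, size_fn, variant, seed_seq):
    rng = np.random.default_rng(seed_seq)
    rand = randomize(network, RandomizationConfig(variant=variant), rng=rng)
    if rand.M == 0:
        return None
    det_seed = int(seed_seq.generate_state(1)[0] % (2**31))
    part = detector(rand, det_seed)
    q = quality_fn(rand, part)
    s = size_fn(rand, part)
    return np.asarray(q, dtype=np.float64), np.asarray(s, dtype=np.float64)


def sample_null_pairs(
    network: Network,
    detector: Callable[[Network, int], Partition],
    quality_fn: Callable[[Network, Partition], np.ndarray],
    size_fn: Callable[[Network, Partition], np.ndarray],
    config: RandomizationConfig,
    workers: int = 1,
) -> tuple[np.ndarray, np.ndarray]:
    """Detect communities in R randomizations and collect their (q, s) pairs.

    ``detector(net, seed) -> Partition`` must be the same algorithm (objective
    and C policy) used on the original network.  ``quality_fn`` / ``size_fn``
    map (network, partition) to per-community arrays.  Returns the pooled
    arrays (q_tilde, s_tilde) of length Cbar, in randomization order —
    identical for any worker count given the same base seed.
    """
    seeds = [child_seed(config.seed, r) for r in range(config.R)]
    if workers == 1:
        results = [
            _one_network_samples(network, detector, quality_fn, size_fn, config.variant, ss)
            for ss in seeds
        ]
    else:
        results = Parallel(n_jobs=workers)(
            delayed(_one_network_samples)(network, detector, quality_fn, size_fn, config.variant, ss)
            for ss in seeds
        )
    skipped = sum(1 for r in results if r is None)
    if skipped:
        warnings.warn(f"{skipped} randomized network(s) had no edges and were skipped")
    qs = [r[0] for r in results if r is not None]
    ss_ = [r[1] for r in results if r is not None]
    if not qs:
        raise ValueError("all randomized networks were empty; cannot build a null ensemble")
    return np.concatenate(qs), np.concatenate(ss_)


def sample_null_ensemble(
    network: Network,
    detector: Callable[[Network, int], Partition],
    quality_fn: Callable[[Network, Partition], np.ndarray],
    size_fn: Callable[[Network, Partition], np.ndarray],
    config: RandomizationConfig,
    workers: int = 1,
):
    """As :func:`sample_null_pairs`, but returns a fitted NullEnsemble."""
    from .qstest import fit_null  # late import: qstest composes on this module

    q, s = sample_null_pairs(network, detector, quality_fn, size_fn, config, workers)
    return fit_null(list(zip(q, s)))
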