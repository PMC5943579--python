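"""LFR-style planted-partition benchmarks and the associated experiments.

The generator emulates the LFR model: node degrees and community sizes follow
truncated power laws, each node keeps an average fraction 1 - mu of its edges
inside its own community, and edges are realized by stub matching (intra
stubs paired within each community, inter stubs paired across communities),
discarding the few conflicting stubs.  mu = 0 therefore yields strictly
intra-community edges and mu = 1 strictly inter-community edges.

Experiments:

* ``tpr_experiment`` — the true-positive-rate curve: apply a significance
  test to the *planted* communities of freshly generated networks over a grid
  of mu and average the per-network fraction judged significant.
* ``agreement_tau`` — the fraction of communities on which two tests agree.
* ``quality_size_scatter`` — pooled (quality, community size) pairs from
  planted communities and communities detected in randomizations, for the
  quality-vs-size correlation that motivates conditioning on size.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .graph_core import Network, Partition
from .quality import community_scores
from .null_model import RandomizationConfig, child_seed, randomize

__all__ = [
    "LFRConfig",
    "TPRRecord",
    "generate_lfr",
    "tpr_experiment",
    "agreement_tau",
    "quality_size_scatter",
    "quality_size_correlation",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class LFRConfig:
    """Planted-partition generator parameters (defaults: the benchmark's
    standard setting of N=1000, <k>=10, k_max=100, exponents 2, community
    sizes 20..200)."""

    N: int = 1000
    avg_degree: float = 10.0
    max_degree: int = 100
    exponent_degree: float = 2.0
    exponent_community: float = 2.0
    community_size_range: tuple[int, int] = (20, 200)
    mu: float = 0.0
    seed: int | None = None
    max_attempts: int = 20

    def __post_init__(self):
        if not 0.0 <= self.mu <= 1.0:
            raise ValueError("mu must be in [0, 1]")
        if self.exponent_degree <= 1 or self.exponent_community <= 1:
            raise ValueError("power-law exponents must be > 1")
        smin, smax = self.community_size_range
        if smin < 1 or smax < smin:
            raise ValueError("invalid community size range")
        if not (self.avg_degree <= self.max_degree <= self.N - 1):
            raise ValueError("need avg_degree <= max_degree <= N - 1")
        if smax > self.N:
            raise ValueError("max community size exceeds N")


@dataclass(frozen=True)
class TPRRecord:
    mu: float
    test: str
    tpr_mean: float
    tpr_sd: float
    n_replicates: int


def _truncated_powerlaw(rng, exponent, lo, hi, size):
    """Integer samples ~ floor of a continuous power law on [lo, hi + 1)."""
    a = 1.0 - exponent
    lo_, hi_ = float(lo), float(hi) + 1.0
    u = rng.random(size)
    x = (lo_**a + u * (hi_**a - lo_**a)) ** (1.0 / a)
    return np.minimum(hi, np.floor(x).astype(np.int64))


def _discretized_mean(exponent, lo, hi):
    """Mean of the floor-discretized truncated power law with lower cutoff lo."""
    a = 1.0 - exponent
    lo_, hi_ = float(lo), float(hi) + 1.0
    z = hi_**a - lo_**a

    def cdf(x):
        x = min(max(x, lo_), hi_)
        return (x**a - lo_**a) / z

    total = 0.0
    for k in range(int(math.floor(lo_)), int(hi_)):
        total += k * (cdf(k + 1.0) - cdf(k))
    return total


def _solve_min_degree(avg_degree, exponent, max_degree):
    lo, hi = 1.0, float(max_degree)
    for _ in range(80):
        mid = 0.5 * (lo + hi)
        if _discretized_mean(exponent, mid, max_degree) < avg_degree:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def _sample_community_sizes(rng, cfg: LFRConfig):
    smin, smax = cfg.community_size_range
    for _ in range(200):
        sizes: list[int] = []
        while sum(sizes) < cfg.N:
            sizes.append(int(_truncated_powerlaw(rng, cfg.exponent_community, smin, smax, 1)[0]))
        excess = sum(sizes) - cfg.N
        if excess == 0:
            return np.asarray(sizes)
        # shave the excess off the largest communities while staying in range
        sizes.sort(reverse=True)
        for i in range(len(sizes)):
            cut = min(excess, sizes[i] - smin)
            sizes[i] -= cut
            excess -= cut
            if excess == 0:
                rng.shuffle(sizes)
                return np.asarray(sizes)
    raise RuntimeError("could not sample community sizes summing to N")


def _assign_nodes(rng, sizes, k_int, allow_capping):
    """Place each node in a community with capacity and room for its internal
    degree (community size must exceed the node's internal degree).

    When ``allow_capping`` (mu > 0), a hub whose internal degree exceeds
    every open community's size is placed in the largest open community and
    its internal degree capped at size - 1 (its surplus becomes inter-community
    stubs) — the standard resolution for hubs at low mixing.
    """
    C = sizes.size
    remaining = sizes.copy()
    labels = np.full(k_int.size, -1, dtype=np.int64)
    k_int = k_int.copy()
    order = np.argsort(-k_int)  # hardest nodes first
    for i in order:
        ok = np.flatnonzero((remaining > 0) & (sizes > k_int[i]))
        if ok.size == 0:
            if not allow_capping:
                return None
            open_ = np.flatnonzero(remaining > 0)
            if open_.size == 0:
                return None
            c = open_[np.argmax(sizes[open_])]
            k_int[i] = sizes[c] - 1
        else:
            c = rng.choice(ok, p=remaining[ok] / remaining[ok].sum())
        labels[i] = c
        remaining[c] -= 1
    return labels, k_int


def _match_stubs(rng, stubs, forbid_same_label=None, existing=None, rounds=50):
    """Pair stubs uniformly; re-pair conflicting pairs (self, duplicate, or
    same-label when forbidden) for a few rounds, then drop leftovers."""
    edges = set() if existing is None else existing
    pool = np.array(stubs, dtype=np.int64)
    for _ in range(rounds):
        if pool.size < 2:
            break
        rng.shuffle(pool)
        if pool.size % 2:
            pool, odd = pool[:-1], pool[-1:]
        else:
            odd = np.empty(0, dtype=np.int64)
        a, b = pool[0::2], pool[1::2]
        bad = a == b
        if forbid_same_label is not None:
            bad |= forbid_same_label[a] == forbid_same_label[b]
        leftover = [odd, a[bad], b[bad]]
        for u, vv in zip(a[~bad], b[~bad]):
            e = (int(u), int(vv)) if u < vv else (int(vv), int(u))
            if e in edges:
                leftover.append(np.array([u, vv], dtype=np.int64))
            else:
                edges.add(e)
        pool = np.concatenate(leftover)
    return edges


def _simple_graph_with_degrees(rng, degrees):
    """Edge list of a simple graph realizing ``degrees`` exactly (edge-switching
    MCMC via igraph), or None if the sequence is not graphical."""
    import random as _pyrandom

    import igraph as ig

    if degrees.sum() == 0:
        return []
    state = _pyrandom.getstate()
    _pyrandom.seed(int(rng.integers(2**31)))
    try:
        g = ig.Graph.Degree_Sequence(list(map(int, degrees)), method="edge_switching_simple")
        return g.get_edgelist()
    except ig.InternalError:
        return None
    finally:
        _pyrandom.setstate(state)


def _generate_once(cfg: LFRConfig, rng):
    kmin = _solve_min_degree(cfg.avg_degree, cfg.exponent_degree, cfg.max_degree)
    d = _truncated_powerlaw(rng, cfg.exponent_degree, kmin, cfg.max_degree, cfg.N)
    if d.sum() % 2:
        d[rng.integers(cfg.N)] += 1
    sizes = _sample_community_sizes(rng, cfg)
    k_int = np.rint((1.0 - cfg.mu) * d).astype(np.int64)
    k_int = np.minimum(k_int, d)
    placed = _assign_nodes(rng, sizes, k_int, allow_capping=cfg.mu > 0)
    if placed is None:
        return None
    labels, k_int = placed
    # per-community intra stub sums must be even
    for c in range(sizes.size):
        members = np.flatnonzero(labels == c)
        if k_int[members].sum() % 2:
            j = members[np.argmax(k_int[members])]
            if k_int[j] == 0:
                return None
            k_int[j] -= 1
            if cfg.mu == 0.0:
                d[j] -= 1  # keep the node fully internal
    k_ext = d - k_int
    if k_ext.sum() % 2:
        j = int(np.argmax(k_ext))
        k_ext[j] -= 1
        d[j] -= 1
    edges: set = set()
    for c in range(sizes.size):
        members = np.flatnonzero(labels == c)
        sub = _simple_graph_with_degrees(rng, k_int[members])
        if sub is None:  # non-graphical within the community: pair stubs and drop conflicts
            edges = _match_stubs(rng, np.repeat(members, k_int[members]), existing=edges)
        else:
            for i, j in sub:
                u, v = int(members[i]), int(members[j])
                edges.add((u, v) if u < v else (v, u))
    if k_ext.sum() > 0:
        stubs = np.repeat(np.arange(cfg.N), k_ext)
        edges = _match_stubs(rng, stubs, forbid_same_label=labels, existing=edges)
    E = np.asarray(sorted(edges), dtype=np.int64) if edges else np.empty((0, 2), dtype=np.int64)
    net = Network.from_index_edges(E, cfg.N)
    if net.M == 0:
        return None
    realized_mean = 2.0 * net.M / cfg.N
    if abs(realized_mean - cfg.avg_degree) > 0.15 * cfg.avg_degree:
        return None
    if (net.degrees == 0).any():
        return None  # LFR nodes have degree >= the min cutoff; retry
    return net, Partition(labels)


def generate_lfr(config: LFRConfig) -> tuple[Network, Partition]:
    """Generate one planted-partition network and its planted communities.

    Retries with fresh sub-seeds (up to ``max_attempts``) when stub matching
    or node placement fails or the realized mean degree drifts more than 15%
    from the target.
    """
    for attempt in range(config.max_attempts):
        rng = np.random.default_rng(child_seed(config.seed, attempt))
        out = _generate_once(config, rng)
        if out is not None:
            return out
    raise RuntimeError(f"LFR generation failed after {config.max_attempts} attempts: {config}")


def _apply_test(name, network, partition, R, seed, qs_objective="mod", qs_size="nodes"):
    from .baselines import l_test_criterion, s_test
    from .qstest import run_qstest

    if name == "l_test":
        return l_test_criterion(network, partition).significant
    if name == "s_test":
        return s_test(network, partition, R=R, seed=seed).significant
    if name == "qs":
        return run_qstest(
            network, partition, objective=qs_objective, size_kind=qs_size, R=R, seed=seed
        ).significant
    raise ValueError(f"unknown test {name!r}")


def tpr_experiment(
    tests,
    mu_grid,
    replicates: int = 10,
    R: int = 100,
    seed: int | None = None,
    lfr_config: LFRConfig | None = None,
) -> list[TPRRecord]:
    """True positive rate of each test over a grid of mixing parameters.

    Each test descriptor is ``"l_test"``, ``"s_test"``, or
    ``("qs", objective, size_kind)``.  For each mu and each of ``replicates``
    fresh networks, the test is applied to the planted communities; the TPR
    is the fraction judged significant, averaged over replicates.
    """
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    base = lfr_config or LFRConfig()
    records = []
    for mu_idx, mu in enumerate(mu_grid):
        per_test: dict[str, list[float]] = {}
        for rep in range(replicates):
            ss = np.random.SeedSequence(seed, spawn_key=(mu_idx, rep))
            gseed = int(ss.generate_state(1)[0] % 2**31)
            net, part = generate_lfr(replace(base, mu=mu, seed=gseed))
            for t in tests:
                if isinstance(t, str):
                    name, args = t, {}
                    label = t
                else:
                    name, args = t[0], {"qs_objective": t[1], "qs_size": t[2]}
                    label = f"qs_{t[1]}_{t[2]}"
                flags = _apply_test(name, net, part, R, gseed, **args)
                per_test.setdefault(label, []).append(float(np.mean(flags)))
        for label, vals in per_test.items():
            records.append(
                TPRRecord(
                    mu=float(mu),
                    test=label,
                    tpr_mean=float(np.mean(vals)),
                    tpr_sd=float(np.std(vals, ddof=1)) if len(vals) > 1 else 0.0,
                    n_replicates=len(vals),
                )
            )
    return records


def tpr_frame(records) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "mu": [r.mu for r in records],
            "test": [r.test for r in records],
            "tpr_mean": [r.tpr_mean for r in records],
            "tpr_sd": [r.tpr_sd for r in records],
            "n_replicates": [r.n_replicates for r in records],
        }
    )


def tpr_plot(records, path):
    """Convenience TPR-vs-mu plot (one line per test) written to ``path``."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    df = tpr_frame(records)
    fig, ax = plt.subplots(figsize=(5, 3.5))
    for test, grp in df.groupby("test"):
        grp = grp.sort_values("mu")
        ax.errorbar(grp["mu"], grp["tpr_mean"], yerr=grp["tpr_sd"], label=test, marker="o")
    ax.set_xlabel(r"mixing parameter $\mu$")
    ax.set_ylabel("true positive rate")
    ax.set_ylim(-0.02, 1.02)
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def agreement_tau(flags_a, flags_b) -> float:
    """Fraction of communities on which two tests agree: (C11 + C00) / C."""
    a = np.asarray(flags_a, dtype=bool)
    b = np.asarray(flags_b, dtype=bool)
    if a.shape != b.shape or a.ndim != 1 or a.size == 0:
        raise ValueError("flag vectors must be equal-length, non-empty 1-D")
    return float((a == b).mean())


def quality_size_scatter(
    lfr_config: LFRConfig | None = None,
    R: int = 20,
    objective: str = "mod",
    seed: int | None = None,
) -> pd.DataFrame:
    """Pooled (q, n_c) pairs from planted communities and from communities
    detected (Louvain / KL as appropriate) in R randomizations.

    Columns: q, n_c, source in {planted, randomized}.
    """
    from .detection import detect

    if R < 1:
        raise ValueError("need at least one randomized network")
    cfg = lfr_config or LFRConfig(community_size_range=(10, 100), mu=0.25)
    net, part = generate_lfr(replace(cfg, seed=seed))
    rows = []
    q, s = community_scores(net, part, objective, "nodes")
    rows += [(float(qq), float(nn), "planted") for qq, nn in zip(q, s)]
    for r in range(R):
        rng = np.random.default_rng(child_seed(seed, 1000 + r))
        rand = randomize(net, RandomizationConfig(), rng=rng)
        if rand.M == 0:
            continue
        det_seed = int(child_seed(seed, 1000 + r).generate_state(1)[0] % 2**31)
        p = detect(rand, objective=objective, C=part.C if objective != "mod" else None, seed=det_seed)
        q, s = community_scores(rand, p, objective, "nodes")
        rows += [(float(qq), float(nn), "randomized") for qq, nn in zip(q, s)]
    if len(rows) < 2:
        raise ValueError("not enough communities pooled to form a scatter")
    return pd.DataFrame(rows, columns=["q", "n_c", "source"])


def quality_size_correlation(table: pd.DataFrame) -> float:
    """Pearson correlation of q with n_c over the pooled scatter."""
    from scipy import stats

    if len(table) < 2:
        raise ValueError("correlation undefined for fewer than 2 communities")
    if table["q"].nunique() < 2 or table["n_c"].nunique() < 2:
        raise ValueError("correlation undefined for a constant column")
    return float(stats.pearsonr(table["q"], table["n_c"])[0])
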