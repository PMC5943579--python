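"""The (q, s)-test: size-corrected significance of individual communities.

A community c with quality q_c and size s_c is compared against the joint
null distribution of (quality, size) pairs of communities detected in
degree-preserving randomizations of the same network.  The joint null is
estimated with a bivariate Gaussian kernel density over the Cbar pooled
pairs, with per-coordinate scales h*sigma_q and h*sigma_s, kernel correlation
gamma equal to the Pearson correlation of the pairs, and Scott's-rule
bandwidth h = Cbar^(-1/6).  The p-value is the conditional tail probability

    p = P(q_tilde >= q_c | s_c)
      = 1 - sum_k w_k Phi(((q_c - q_k)/(h s_q) - gamma (s_c - s_k)/(h s_s))
                          / sqrt(1 - gamma^2)) / sum_k w_k,

with Gaussian size weights w_k = exp(-((s_c - s_k)/(sqrt(2) h s_s))^2) — the
closed form of the ratio of KDE integrals over q.  Community c is significant
if p <= alpha, where alpha = 1 - (1 - alpha')^(1/C) is the Sidak-corrected
level for testing the C communities of the partition at family level alpha'.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import ndtr

from .graph_core import Network, Partition
from .quality import SIZE_KINDS, community_aggregates, community_scores
from .null_model import RandomizationConfig, sample_null_pairs

__all__ = [
    "NullEnsemble",
    "TestResult",
    "DegenerateEnsembleError",
    "fit_null",
    "conditional_p",
    "sidak_alpha",
    "run_qstest",
]

logger = logging.getLogger(__name__)

_GAMMA_CLIP = 1.0 - 1e-8
# exp underflows to 0 past ~745 in double precision
_LOG_UNDERFLOW = 700.0


class DegenerateEnsembleError(ValueError):
    """Null ensemble has zero variance in q or s; increase R."""


@dataclass(frozen=True)
class NullEnsemble:
    """The fitted null: Cbar (quality, size) samples and their KDE parameters."""

    q_tilde: np.ndarray
    s_tilde: np.ndarray
    c_bar: int
    q_mean: float
    s_mean: float
    sigma_q: float
    sigma_s: float
    gamma: float
    h: float


def fit_null(samples) -> NullEnsemble:
    """Fit the bivariate-Gaussian KDE null from (q_tilde, s_tilde) samples.

    Standard deviations use the unbiased (Cbar - 1) denominator; gamma is the
    Pearson correlation of the samples; h = Cbar^(-1/6) (Scott's rule).  A
    perfectly correlated ensemble has gamma clipped to +/-(1 - 1e-8) with a
    warning; zero variance in either coordinate is a hard error.
    """
    arr = np.asarray(samples, dtype=np.float64)
    if arr.ndim != 2 or arr.shape[1] != 2:
        arr = np.column_stack([np.asarray(s, dtype=np.float64) for s in samples])
    q, s = arr[:, 0], arr[:, 1]
    c_bar = q.size
    if c_bar < 2:
        raise ValueError(f"need at least 2 null samples, got {c_bar}")
    q_mean, s_mean = float(q.mean()), float(s.mean())
    dq, ds = q - q_mean, s - s_mean
    sigma_q = math.sqrt(float(dq @ dq) / (c_bar - 1))
    sigma_s = math.sqrt(float(ds @ ds) / (c_bar - 1))
    if sigma_q == 0.0 or sigma_s == 0.0:
        raise DegenerateEnsembleError(
            "null ensemble is degenerate (zero variance in q or s); "
            "increase the number of randomized networks R"
        )
    gamma = float(dq @ ds) / math.sqrt(float(dq @ dq) * float(ds @ ds))
    if abs(gamma) >= 1.0 - 1e-12:
        warnings.warn("null (q, s) samples are perfectly correlated; clipping gamma")
        gamma = math.copysign(_GAMMA_CLIP, gamma)
    h = c_bar ** (-1.0 / 6.0)
    return NullEnsemble(
        q_tilde=q.copy(),
        s_tilde=s.copy(),
        c_bar=c_bar,
        q_mean=q_mean,
        s_mean=s_mean,
        sigma_q=sigma_q,
        sigma_s=sigma_s,
        gamma=gamma,
        h=h,
    )


def conditional_p(ensemble: NullEnsemble, q_c: float, s_c: float) -> float:
    """P(q_tilde >= q_c | s_c) under the KDE null (closed form, in [0, 1])."""
    hs = ensemble.h * ensemble.sigma_s
    hq = ensemble.h * ensemble.sigma_q
    zs = (s_c - ensemble.s_tilde) / hs
    log_w = -0.5 * zs * zs  # log of exp(-((s_c - s_k)/(sqrt(2) h sigma_s))^2)
    shift = log_w.max()
    if shift < -_LOG_UNDERFLOW:
        raise ValueError(
            f"size s_c={s_c} lies outside the support of the null size distribution; "
            "the p-value would be an unsafe extrapolation"
        )
    w = np.exp(log_w - shift)
    zq = (q_c - ensemble.q_tilde) / hq
    g = ensemble.gamma
    phi = ndtr((zq - g * zs) / math.sqrt(1.0 - g * g))
    p = 1.0 - float(w @ phi) / float(w.sum())
    return min(max(p, 0.0), 1.0)


def sidak_alpha(alpha_prime: float, C: int) -> float:
    """Sidak-corrected per-community level: alpha = 1 - (1 - alpha')^(1/C)."""
    if not 0.0 <= alpha_prime <= 1.0:
        raise ValueError("alpha_prime must be in [0, 1]")
    if C < 1:
        raise ValueError("C must be >= 1")
    if C == 1:
        return alpha_prime  # exact identity; 1 - (1 - a) would round
    return 1.0 - (1.0 - alpha_prime) ** (1.0 / C)


@dataclass
class TestResult:
    """Per-community test outcome plus the global testing parameters."""

    community: np.ndarray  # 1..C
    n_nodes: np.ndarray
    volume: np.ndarray
    q_value: np.ndarray
    size_value: np.ndarray
    p_value: np.ndarray
    significant: np.ndarray
    alpha: float
    alpha_prime: float
    C: int
    ensemble: NullEnsemble | None = None
    test_name: str = "qs"
    objective: str = "mod"
    size_kind: str = "nodes"
    extra: dict = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "community_id": self.community,
                "n_nodes": self.n_nodes,
                "volume": self.volume,
                "q_value": self.q_value,
                "size_value": self.size_value,
                "p_value": self.p_value,
                "alpha": self.alpha,
                "significant": self.significant,
            }
        )


def run_qstest(
    network: Network,
    partition: Partition,
    objective: str = "mod",
    size_kind: str = "nodes",
    R: int = 500,
    alpha_prime: float = 0.05,
    seed: int | None = None,
    workers: int = 1,
    variant: str = "chung_lu",
    detected_internally: bool = True,
) -> TestResult:
    """Run the (q, s)-test on every community of ``partition``.

    The null ensemble is built by detecting communities in R degree-preserving
    randomizations with the detector matched to ``objective`` (Louvain for
    ``mod``; the KL search with the partition's C otherwise), then each
    community's (q_c, s_c) is scored against the KDE null.  Deterministic for
    a fixed ``seed`` and any ``workers`` count.
    """
    from .detection import detect_kl, detect_louvain, DetectionConfig

    if partition.labels.size != network.N:
        raise ValueError("partition does not cover the network")
    if size_kind not in SIZE_KINDS:
        raise ValueError(f"unknown size measure {size_kind!r}")
    if not detected_internally:
        warnings.warn(
            "membership was supplied externally; the null ensemble assumes the "
            f"partition optimizes the {objective!r} objective"
        )

    if objective == "mod":
        def detector(net, det_seed):
            return detect_louvain(net, seed=det_seed)
    else:
        C_fixed = partition.C

        def detector(net, det_seed):
            return detect_kl(net, DetectionConfig(objective=objective, C=C_fixed, seed=det_seed))

    def quality_fn(net, part):
        return community_scores(net, part, objective, size_kind)[0]

    def size_fn(net, part):
        return community_scores(net, part, objective, size_kind)[1]

    q_t, s_t = sample_null_pairs(
        network,
        detector,
        quality_fn,
        size_fn,
        RandomizationConfig(variant=variant, seed=seed, R=R),
        workers=workers,
    )
    ensemble = fit_null(np.column_stack([q_t, s_t]))
    logger.info(
        "null ensemble: Cbar=%d gamma=%.4f h=%.4f", ensemble.c_bar, ensemble.gamma, ensemble.h
    )

    q, s = community_scores(network, partition, objective, size_kind)
    _, n, vol = community_aggregates(network, partition)
    p = np.array([conditional_p(ensemble, qc, sc) for qc, sc in zip(q, s)])
    alpha = sidak_alpha(alpha_prime, partition.C)
    return TestResult(
        community=np.arange(1, partition.C + 1),
        n_nodes=n,
        volume=vol,
        q_value=q,
        size_value=s,
        p_value=p,
        significant=p <= alpha,
        alpha=alpha,
        alpha_prime=alpha_prime,
        C=partition.C,
        ensemble=ensemble,
        objective=objective,
        size_kind=size_kind,
    )
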