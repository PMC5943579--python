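import math

import numpy as np
import pytest
from scipy import integrate, stats

from commsig import (
    DegenerateEnsembleError,
    Network,
    Partition,
    conditional_p,
    fit_null,
    run_qstest,
    sidak_alpha,
)

from conftest import random_graph


def gaussian_kernel(x1, x2, gamma):
    """Correlated bivariate standard normal density (the KDE kernel)."""
    z = (x1 * x1 - 2 * gamma * x1 * x2 + x2 * x2) / (2 * (1 - gamma * gamma))
    return math.exp(-z) / (2 * math.pi * math.sqrt(1 - gamma * gamma))


def p_by_quadrature(ens, q_c, s_c):
    """Oracle: ratio of numerically integrated KDE integrals over quality.

    Works in the standardized coordinate x1 = (q - q_k) / (sigma_q h) per
    kernel; never uses the closed-form partial integral.
    """
    num = den = 0.0
    for qk, sk in zip(ens.q_tilde, ens.s_tilde):
        xs = (s_c - sk) / (ens.sigma_s * ens.h)
        y = (q_c - qk) / (ens.sigma_q * ens.h)
        f = lambda x1: gaussian_kernel(x1, xs, ens.gamma)
        lo = ens.gamma * xs - 40
        hi = ens.gamma * xs + 40
        num += integrate.quad(f, max(y, lo), hi, limit=200)[0] if y < hi else 0.0
        den += integrate.quad(f, lo, hi, limit=200)[0]
    return num / den


def random_ensemble(rng, n=50, gamma_target=None):
    g = rng.uniform(-0.9, 0.9) if gamma_target is None else gamma_target
    cov = [[1.0, g], [g, 1.0]]
    xy = rng.multivariate_normal([0.0, 10.0], cov, size=n)
    xy[:, 1] *= rng.uniform(0.5, 3.0)
    return fit_null(xy)


class TestFitNull:
    def test_scott_bandwidth_power_of_two(self):
        rng = np.random.default_rng(0)
        ens = random_ensemble(rng, n=64)
        assert ens.h == pytest.approx(0.5)
        assert ens.c_bar == 64

    def test_symmetric_four_point_ensemble(self):
        ens = fit_null([(-1, 9), (1, 9), (-1, 11), (1, 11)])
        assert ens.gamma == pytest.approx(0.0)
        assert ens.q_mean == pytest.approx(0.0)
        assert ens.s_mean == pytest.approx(10.0)

    @pytest.mark.parametrize("seed", range(5))
    def test_gamma_matches_pearson_oracle(self, seed):
        rng = np.random.default_rng(seed)
        xy = rng.normal(size=(40, 2)) @ [[1, 0.6], [0, 0.8]]
        ens = fit_null(xy)
        assert ens.gamma == pytest.approx(stats.pearsonr(xy[:, 0], xy[:, 1])[0], abs=1e-12)
        assert ens.sigma_q == pytest.approx(np.std(xy[:, 0], ddof=1), abs=1e-12)

    def test_degenerate_variance_raises(self):
        with pytest.raises(DegenerateEnsembleError):
            fit_null([(1.0, 3.0), (1.0, 4.0), (1.0, 5.0)])

    def test_perfect_correlation_clipped_with_warning(self):
        with pytest.warns(UserWarning, match="clipping"):
            ens = fit_null([(0.0, 0.0), (1.0, 1.0), (2.0, 2.0)])
        assert abs(ens.gamma) < 1.0

    def test_moments_recomputable_from_samples(self):
        rng = np.random.default_rng(3)
        ens = random_ensemble(rng, n=37)
        assert ens.q_mean == pytest.approx(ens.q_tilde.mean(), abs=1e-12)
        assert ens.sigma_s == pytest.approx(np.std(ens.s_tilde, ddof=1), abs=1e-12)
        assert ens.h == pytest.approx(37 ** (-1 / 6))


class TestConditionalP:
    def test_symmetric_ensemble_center_is_half(self):
        ens = fit_null([(-1, 9), (1, 9), (-1, 11), (1, 11)])
        assert conditional_p(ens, 0.0, 10.0) == pytest.approx(0.5)

    def test_extreme_quality_limits(self):
        ens = random_ensemble(np.random.default_rng(1))
        s0 = float(ens.s_tilde.mean())
        assert conditional_p(ens, 1e6, s0) == pytest.approx(0.0, abs=1e-12)
        assert conditional_p(ens, -1e6, s0) == pytest.approx(1.0, abs=1e-12)

    @pytest.mark.parametrize("seed", range(4))
    def test_matches_quadrature_oracle(self, seed):
        rng = np.random.default_rng(seed)
        ens = random_ensemble(rng)
        for _ in range(5):
            q_c = rng.normal()
            s_c = float(rng.choice(ens.s_tilde)) + rng.normal() * ens.sigma_s * 0.3
            assert conditional_p(ens, q_c, s_c) == pytest.approx(
                p_by_quadrature(ens, q_c, s_c), abs=1e-6
            )

    def test_monotone_nonincreasing_in_quality(self):
        rng = np.random.default_rng(2)
        ens = random_ensemble(rng)
        s0 = float(np.median(ens.s_tilde))
        grid = np.linspace(-4, 4, 81)
        ps = [conditional_p(ens, q, s0) for q in grid]
        assert all(a >= b - 1e-12 for a, b in zip(ps, ps[1:]))

    def test_size_scale_invariance(self):
        """Multiplying all sizes by a positive constant leaves p unchanged."""
        rng = np.random.default_rng(4)
        xy = rng.multivariate_normal([0, 50], [[1, 0.5], [0.5, 4]], size=80)
        ens1 = fit_null(xy)
        xy2 = xy.copy()
        xy2[:, 1] *= 7.3
        ens2 = fit_null(xy2)
        for q_c, s_c in [(0.1, 48.0), (-0.5, 55.0), (1.2, 50.0)]:
            assert conditional_p(ens1, q_c, s_c) == pytest.approx(
                conditional_p(ens2, q_c, 7.3 * s_c), abs=1e-12
            )

    def test_size_far_outside_support_raises(self):
        ens = fit_null([(-1, 9), (1, 9), (-1, 11), (1, 11)])
        with pytest.raises(ValueError, match="support"):
            conditional_p(ens, 0.0, 1e6)


class TestSidak:
    def test_single_community_is_identity(self):
        assert sidak_alpha(0.05, 1) == pytest.approx(0.05)

    def test_perfect_square_case(self):
        assert sidak_alpha(0.75, 2) == pytest.approx(0.5)

    def test_high_precision_oracle(self):
        from mpmath import mp, mpf

        mp.dps = 50
        expected = float(1 - (1 - mpf("0.05")) ** (mpf(1) / 31))
        assert sidak_alpha(0.05, 31) == pytest.approx(expected, abs=1e-15)

    @pytest.mark.parametrize("C", [1, 2, 5, 40])
    def test_bounded_by_family_level(self, C):
        a = sidak_alpha(0.05, C)
        assert 0 < a <= 0.05 + 1e-15
        assert (a == 0.05) == (C == 1)

    def test_invalid_inputs_raise(self):
        with pytest.raises(ValueError):
            sidak_alpha(1.5, 3)
        with pytest.raises(ValueError):
            sidak_alpha(0.05, 0)


@pytest.fixture(scope="module")
def toy_result():
    net = Network.from_edges(
        [(0, 1), (1, 2), (0, 2), (3, 4), (4, 5), (3, 5), (2, 3), (5, 6), (6, 7), (7, 5)]
    )
    part = Partition([1, 1, 1, 2, 2, 2, 2, 2])
    return net, part, run_qstest(net, part, R=40, seed=13)


class TestRunQstest:
    def test_output_schema_and_ranges(self, toy_result):
        net, part, res = toy_result
        assert res.C == 2
        assert np.all((res.p_value >= 0) & (res.p_value <= 1))
        assert res.alpha == pytest.approx(sidak_alpha(0.05, 2))
        assert np.array_equal(res.significant, res.p_value <= res.alpha)
        df = res.to_frame()
        assert list(df.columns) == [
            "community_id", "n_nodes", "volume", "q_value",
            "size_value", "p_value", "alpha", "significant",
        ]

    def test_deterministic_and_worker_invariant(self, toy_result):
        net, part, res = toy_result
        res2 = run_qstest(net, part, R=40, seed=13, workers=2)
        assert np.array_equal(res.p_value, res2.p_value)

    def test_single_community_alpha_equals_family_level(self):
        net = random_graph(np.random.default_rng(6), 12, 0.4)
        part = Partition(np.ones(net.N, dtype=int))
        res = run_qstest(net, part, R=30, seed=2)
        assert res.alpha == pytest.approx(0.05)

    def test_external_membership_warns(self, toy_result):
        net, part, _ = toy_result
        with pytest.warns(UserWarning, match="externally"):
            run_qstest(net, part, R=10, seed=1, detected_internally=False)
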