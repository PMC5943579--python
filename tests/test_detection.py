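import itertools

import numpy as np
import pytest

from commsig import (
    DetectionConfig,
    Network,
    Partition,
    delta_Q,
    detect,
    detect_kl,
    detect_louvain,
    total_quality,
)

from conftest import random_graph, random_partition


def exhaustive_best_Q(net: Network, C: int, objective: str) -> float:
    """Brute force over all C^N label assignments that use every label
    (all C communities non-empty)."""
    best = -np.inf
    for labels in itertools.product(range(C), repeat=net.N):
        if len(set(labels)) < C:
            continue
        st = _Q_of_labels(net, np.array(labels), C, objective)
        best = max(best, st)
    return best


def _Q_of_labels(net, labels, C, objective):
    from commsig.quality import q_from_aggregates

    n = np.bincount(labels, minlength=C)
    vol = np.bincount(labels, weights=net.degrees, minlength=C)
    lu, lv = labels[net.edges[:, 0]], labels[net.edges[:, 1]]
    m = np.bincount(lu[lu == lv], minlength=C)
    return float(q_from_aggregates(m, n, vol, objective, net.M).sum())


def exhaustive_best_modularity(net: Network) -> float:
    """Brute force over all set partitions of the nodes."""
    def set_partitions(items):
        if not items:
            yield []
            return
        head, rest = items[0], items[1:]
        for smaller in set_partitions(rest):
            for i in range(len(smaller)):
                yield smaller[:i] + [smaller[i] + [head]] + smaller[i + 1 :]
            yield [[head]] + smaller

    best = -np.inf
    for blocks in set_partitions(list(range(net.N))):
        labels = np.empty(net.N, dtype=int)
        for c, block in enumerate(blocks):
            labels[block] = c
        best = max(best, _Q_of_labels(net, labels, len(blocks), "mod"))
    return best


class TestLouvain:
    def test_two_disjoint_triangles_found_exactly(self, two_triangles):
        net, _ = two_triangles
        part = detect_louvain(net, seed=0)
        assert part.C == 2
        assert len(set(part.labels[:3])) == 1 and len(set(part.labels[3:])) == 1
        Q = total_quality(net, part, "mod")
        assert Q == pytest.approx(0.5)
        assert Q == pytest.approx(exhaustive_best_modularity(net))

    def test_k4_single_community_is_optimal(self):
        net = Network.from_edges([(i, j) for i in range(4) for j in range(i + 1, 4)])
        part = detect_louvain(net, seed=0)
        Q = total_quality(net, part, "mod")
        assert Q == pytest.approx(exhaustive_best_modularity(net))
        assert part.C == 1

    def test_single_edge_graph(self):
        net = Network.from_edges([(0, 1)])
        part = detect_louvain(net, seed=0)
        assert part.C == 1

    def test_deterministic_under_seed(self):
        net = random_graph(np.random.default_rng(5), 30, 0.15)
        p1 = detect_louvain(net, seed=11)
        p2 = detect_louvain(net, seed=11)
        assert np.array_equal(p1.labels, p2.labels)

    def test_empty_graph_raises(self):
        net = Network.from_edges([], nodes=[0, 1])
        with pytest.raises(ValueError):
            detect_louvain(net)


class TestKernighanLin:
    def test_disjoint_triangles_exp_reaches_global_max(self, two_triangles):
        net, _ = two_triangles
        part = detect_kl(net, DetectionConfig(objective="exp", C=2, seed=0))
        assert total_quality(net, part, "exp") == pytest.approx(0.0)

    def test_barbell_conductance_optimum(self, barbell):
        net, _ = barbell
        best = max(
            total_quality(net, detect_kl(net, DetectionConfig(objective="cnd", C=2, seed=s)), "cnd")
            for s in range(5)
        )
        assert best == pytest.approx(-2 / 7)
        assert best == pytest.approx(exhaustive_best_Q(net, 2, "cnd"))

    def test_single_community_budget_is_forced(self):
        net = random_graph(np.random.default_rng(2), 8)
        part = detect_kl(net, DetectionConfig(objective="int", C=1, seed=0))
        assert part.C == 1
        assert total_quality(net, part, "int") == pytest.approx(2 * net.M / net.N)

    def test_budget_larger_than_n_raises(self):
        net = Network.from_edges([(0, 1)])
        with pytest.raises(ValueError):
            detect_kl(net, DetectionConfig(objective="int", C=3, seed=0))

    @pytest.mark.parametrize("objective", ["mod", "int", "exp", "cnd"])
    def test_reaches_local_optimum_no_single_move_improves(self, objective):
        rng = np.random.default_rng(7)
        net = random_graph(rng, 12, 0.3)
        part = detect_kl(net, DetectionConfig(objective=objective, C=3, seed=3))
        sizes = part.sizes()
        for i in range(net.N):
            if sizes[part.labels[i] - 1] <= 1:
                continue  # moving would destroy the community: inadmissible
            for lab in range(1, part.C + 1):
                if lab != part.labels[i]:
                    assert delta_Q(net, part, i, lab, objective) <= 1e-10


class TestDeltaQ:
    def test_identity_move_is_zero(self, barbell):
        net, part = barbell
        assert delta_Q(net, part, 0, 1, "cnd") == 0.0

    def test_barbell_bridge_move_matches_full_recompute(self, barbell):
        net, part = barbell
        moved = Partition([1, 1, 1, 1, 2, 2])  # node 3 joins community 1
        expected = total_quality(net, moved, "cnd") - total_quality(net, part, "cnd")
        assert delta_Q(net, part, 3, 1, "cnd") == pytest.approx(expected, abs=1e-10)

    def test_isolated_node_move_changes_only_size_terms(self):
        # moving an isolated node under 'int' changes each community's 2e/n term only
        net = Network.from_edges([(0, 1), (1, 2), (3, 4)], nodes=[0, 1, 2, 3, 4, 5])
        part = Partition([1, 1, 1, 2, 2, 2])
        m1, m2 = 2, 1  # intra edges of the two communities
        expected = (2 * m1 / 4 - 2 * m1 / 3) + (2 * m2 / 2 - 2 * m2 / 3)
        assert delta_Q(net, part, 5, 1, "int") == pytest.approx(expected, abs=1e-12)

    @pytest.mark.parametrize("objective", ["mod", "int", "exp", "cnd"])
    def test_agrees_with_full_recompute_on_random_moves(self, objective):
        """250 random (graph, partition, move) fixtures per objective, 1e-10."""
        rng = np.random.default_rng(17)
        for _ in range(250):
            n = int(rng.integers(4, 12))
            net = random_graph(rng, n, 0.4)
            part = random_partition(rng, n, int(rng.integers(2, 5)))
            if part.C < 2:
                continue
            i = int(rng.integers(n))
            new = int(rng.integers(1, part.C + 1))
            if new == part.labels[i]:
                continue
            labels2 = part.labels.copy()
            labels2[i] = new
            # full recompute with the same label space (C fixed, possibly empty)
            before = _Q_of_labels(net, part.labels - 1, part.C, objective)
            after = _Q_of_labels(net, labels2 - 1, part.C, objective)
            assert delta_Q(net, part, i, new, objective) == pytest.approx(
                after - before, abs=1e-10
            )


def test_detect_dispatches_and_derives_C():
    net = random_graph(np.random.default_rng(9), 20, 0.2)
    p_mod = detect(net, "mod", seed=4)
    p_cnd = detect(net, "cnd", seed=4)  # C derived from the Louvain run
    assert p_cnd.C <= p_mod.C
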