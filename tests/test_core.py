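import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from netmoss.core import (
    connection_strength,
    detect_modules,
    intersect_partitions,
    linear_transform,
    module_mean_distance,
    netmoss_scores,
    pick_soft_threshold,
    run_netmoss_from_matrices,
    scale_free_fit,
    topological_overlap,
    weighted_adjacency,
    ModulePartition,
)
from netmoss.simulate import SimulationSpec, simulate_pair
from sklearn.metrics import adjusted_rand_score
from .conftest import make_network


def random_adjacency(n, rng, density=1.0):
    a = rng.uniform(0, 1, (n, n)) * (rng.uniform(0, 1, (n, n)) < density)
    a = (a + a.T) / 2
    np.fill_diagonal(a, 0.0)
    return a


class TestLinearTransform:
    @pytest.mark.parametrize("c,s", [(-1.0, 0.0), (0.0, 0.5), (1.0, 1.0), (0.2, 0.6)])
    def test_values(self, c, s):
        assert linear_transform(np.array([[c]]))[0, 0] == pytest.approx(s)

    def test_monotone(self):
        rng = np.random.default_rng(0)
        c = np.sort(rng.uniform(-1, 1, 50))
        s = linear_transform(c)
        assert np.all(np.diff(s) >= 0)


class TestWeightedAdjacency:
    def test_power_values(self):
        s = np.array([[0.0, 0.5], [0.5, 0.0]])
        assert weighted_adjacency(s, 2)[0, 1] == pytest.approx(0.25)
        s = np.array([[0.0, 0.8], [0.8, 0.0]])
        assert weighted_adjacency(s, 6)[0, 1] == pytest.approx(0.262144)

    def test_beta_one_is_identity_off_diagonal(self):
        rng = np.random.default_rng(1)
        s = rng.uniform(0, 1, (4, 4))
        a = weighted_adjacency(s, 1)
        off = ~np.eye(4, dtype=bool)
        np.testing.assert_allclose(a[off], s[off])
        assert np.all(np.diag(a) == 0)


class TestPickSoftThreshold:
    def test_single_candidate_returned(self):
        rng = np.random.default_rng(2)
        s = linear_transform(np.clip(rng.normal(0, 0.3, (12, 12)), -1, 1))
        s = (s + s.T) / 2
        assert pick_soft_threshold(s, [2]) == 2

    def test_result_in_candidate_list(self):
        rng = np.random.default_rng(3)
        s = rng.uniform(0, 1, (15, 15))
        s = (s + s.T) / 2
        candidates = [1, 3, 7, 12]
        import warnings
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            assert pick_soft_threshold(s, candidates) in candidates

    def test_chosen_beta_beats_beta_one_on_modular_matrix(self):
        pair = simulate_pair(SimulationSpec(n_taxa=100, module_sizes=(60, 40), seed=4))
        s = linear_transform(pair.control_corr.to_numpy())
        import warnings
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            beta = pick_soft_threshold(s)
        fit_chosen = scale_free_fit(weighted_adjacency(s, beta))
        fit_one = scale_free_fit(weighted_adjacency(s, 1))
        assert fit_chosen >= fit_one

    def test_too_few_nodes_rejected(self):
        with pytest.raises(ValueError):
            pick_soft_threshold(np.eye(3))


class TestConnectionStrength:
    def test_plain_row_sum(self):
        a = np.array([[0, 0.2, 0.4], [0.2, 0, 0.1], [0.4, 0.1, 0]])
        np.testing.assert_allclose(connection_strength(a), [0.6, 0.3, 0.5])

    def test_all_neighbors_in_module_agree_with_plain(self):
        a = np.array([[0, 0.5], [0.5, 0]])
        part = ModulePartition(labels=np.array([0, 0]))
        np.testing.assert_allclose(
            connection_strength(a, part), connection_strength(a)
        )

    def test_balanced_within_between_gives_zero(self):
        # node 0: 0.3 inside (node 1), 0.3 outside (node 2)
        a = np.array([[0, 0.3, 0.3], [0.3, 0, 0], [0.3, 0, 0]])
        part = ModulePartition(labels=np.array([0, 0, 1]))
        assert connection_strength(a, part)[0] == pytest.approx(0.0)

    def test_four_node_hand_sums(self):
        a = np.array(
            [
                [0.0, 0.6, 0.1, 0.2],
                [0.6, 0.0, 0.3, 0.0],
                [0.1, 0.3, 0.0, 0.5],
                [0.2, 0.0, 0.5, 0.0],
            ]
        )
        part = ModulePartition(labels=np.array([0, 0, 1, 1]))
        # node0: within 0.6, between 0.1+0.2 -> 0.3; node2: within 0.5, between 0.4 -> 0.1
        np.testing.assert_allclose(
            connection_strength(a, part), [0.3, 0.3, 0.1, 0.3], atol=1e-12
        )

    def test_partition_must_cover_nodes(self):
        with pytest.raises(ValueError):
            connection_strength(np.zeros((3, 3)), ModulePartition(labels=np.array([0, 0])))


class TestTopologicalOverlap:
    def test_complete_graph_full_overlap(self):
        a = 1.0 - np.eye(3)
        tom = topological_overlap(a)
        off = ~np.eye(3, dtype=bool)
        np.testing.assert_allclose(tom.omega[off], 1.0)
        np.testing.assert_allclose(tom.dist[off], 0.0)

    def test_isolated_pair(self):
        w = 0.37
        a = np.zeros((4, 4))
        a[0, 1] = a[1, 0] = w
        tom = topological_overlap(a)
        assert tom.omega[0, 1] == pytest.approx(w)
        assert tom.omega[2, 3] == 0.0  # fully isolated pair

    def test_triangle_hand_value(self):
        a = np.full((3, 3), 0.5)
        np.fill_diagonal(a, 0.0)
        tom = topological_overlap(a)
        # (0.25 + 0.5) / (1 + 1 - 0.5) = 0.5
        assert tom.omega[0, 1] == pytest.approx(0.5)

    def test_matches_brute_force_on_random_graphs(self):
        rng = np.random.default_rng(5)
        for _ in range(10):
            a = random_adjacency(6, rng, density=0.7)
            tom = topological_overlap(a)
            n = 6
            for i in range(n):
                for j in range(n):
                    if i == j:
                        continue
                    l_ij = sum(a[i, u] * a[u, j] for u in range(n) if u not in (i, j))
                    k_i = a[i].sum()
                    k_j = a[j].sum()
                    denom = min(k_i, k_j) + 1 - a[i, j]
                    expected = (l_ij + a[i, j]) / denom if denom > 0 else 0.0
                    assert tom.omega[i, j] == pytest.approx(min(expected, 1.0), abs=1e-10)

    @given(seed=st.integers(0, 100))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_omega_within_unit_interval(self, seed):
        rng = np.random.default_rng(seed)
        a = random_adjacency(8, rng, density=0.5)
        tom = topological_overlap(a)
        assert tom.omega.min() >= 0.0
        assert tom.omega.max() <= 1.0
        np.testing.assert_allclose(tom.omega, tom.omega.T, atol=1e-12)


class TestDetectModules:
    def test_two_perfect_blocks(self):
        n1, n2 = 6, 5
        dist = np.ones((n1 + n2, n1 + n2))
        dist[:n1, :n1] = 0.0
        dist[n1:, n1:] = 0.0
        np.fill_diagonal(dist, 0.0)
        part = detect_modules(dist)
        assert part.n_modules == 2
        assert len(set(part.labels[:n1])) == 1
        assert len(set(part.labels[n1:])) == 1
        assert part.labels[0] != part.labels[-1]

    def test_all_equal_distances_single_module(self):
        dist = np.full((10, 10), 0.7)
        np.fill_diagonal(dist, 0.0)
        part = detect_modules(dist)
        assert part.n_modules == 1

    def test_fewer_nodes_than_min_size_single_module(self):
        dist = np.array([[0, 1, 1], [1, 0, 1], [1, 1, 0]], dtype=float)
        with pytest.warns(UserWarning, match="min_module_size"):
            part = detect_modules(dist, min_module_size=5)
        assert part.n_modules == 1

    def test_planted_modules_recovered(self):
        """ARI >= 0.9 against planted block labels across seeds."""
        aris = []
        for seed in range(5):
            pair = simulate_pair(
                SimulationSpec(n_taxa=100, module_sizes=(60, 40), seed=seed)
            )
            s = linear_transform(pair.control_corr.to_numpy())
            tom = topological_overlap(weighted_adjacency(s, 6))
            part = detect_modules(tom.dist)
            truth = np.array([0] * 60 + [1] * 40)
            aris.append(adjusted_rand_score(truth, part.labels))
        assert np.mean(aris) >= 0.9

    def test_deterministic(self):
        rng = np.random.default_rng(6)
        d = rng.uniform(0, 1, (20, 20))
        d = (d + d.T) / 2
        np.fill_diagonal(d, 0.0)
        a = detect_modules(d)
        b = detect_modules(d)
        np.testing.assert_array_equal(a.labels, b.labels)


class TestIntersectPartitions:
    def test_identical_partitions(self):
        p = ModulePartition(labels=np.array([0, 0, 1, 1, 2]))
        cells = intersect_partitions(p, p)
        assert cells.K == 3

    def test_single_health_module_crossed_with_m(self):
        p1 = ModulePartition(labels=np.zeros(6, dtype=int))
        p2 = ModulePartition(labels=np.array([0, 0, 1, 1, 2, 2]))
        assert intersect_partitions(p1, p2).K == 3

    def test_crossed_two_by_two(self):
        ph = ModulePartition(labels=np.array([0, 0, 0, 1, 1, 1]))
        pd_ = ModulePartition(labels=np.array([0, 0, 1, 1, 0, 0]))
        cells = intersect_partitions(ph, pd_)
        got = sorted(tuple(c) for c in cells.cells)
        assert got == [(0, 1), (2,), (3,), (4, 5)]
        assert cells.K == 4
        # K <= m * n bound
        assert cells.K <= ph.n_modules * pd_.n_modules

    def test_node_set_mismatch_rejected(self):
        with pytest.raises(ValueError):
            intersect_partitions(
                ModulePartition(labels=np.zeros(3, dtype=int)),
                ModulePartition(labels=np.zeros(4, dtype=int)),
            )


class TestModuleMeanDistance:
    def test_zero_distance_matrix(self):
        cells = intersect_partitions(
            ModulePartition(labels=np.array([0, 0, 1])),
            ModulePartition(labels=np.array([0, 0, 1])),
        )
        out = module_mean_distance(np.zeros((3, 3)), cells)
        np.testing.assert_array_equal(out, np.zeros((3, 2)))

    def test_singleton_cell_mean(self):
        dist = np.array([[0, 0.4], [0.4, 0]])
        cells = intersect_partitions(
            ModulePartition(labels=np.array([0, 1])),
            ModulePartition(labels=np.array([0, 1])),
        )
        out = module_mean_distance(dist, cells)
        # node 0 to cell {1} = 0.4; node 0 to own singleton cell {0} = 0
        assert out[0, 1] == pytest.approx(0.4)
        assert out[0, 0] == 0.0

    def test_five_node_hand_averages(self):
        rng = np.random.default_rng(7)
        dist = rng.uniform(0, 1, (5, 5))
        dist = (dist + dist.T) / 2
        np.fill_diagonal(dist, 0.0)
        cells = intersect_partitions(
            ModulePartition(labels=np.array([0, 0, 0, 1, 1])),
            ModulePartition(labels=np.array([0, 0, 0, 1, 1])),
        )
        out = module_mean_distance(dist, cells)
        cell0, cell1 = [0, 1, 2], [3, 4]
        for i in range(5):
            members0 = [j for j in cell0 if j != i]
            members1 = [j for j in cell1 if j != i]
            assert out[i, 0] == pytest.approx(np.mean([dist[i, j] for j in members0]))
            assert out[i, 1] == pytest.approx(np.mean([dist[i, j] for j in members1]))


class TestNetmossScores:
    def _cells(self, ph, pd_):
        return intersect_partitions(ph, pd_)

    def test_identical_states_score_zero(self):
        rng = np.random.default_rng(8)
        d = rng.uniform(0, 1, (6, 3))
        ph = ModulePartition(labels=np.array([0, 0, 1, 1, 2, 2]))
        cells = self._cells(ph, ph)
        res = netmoss_scores(d[:, : cells.K], d[:, : cells.K], cells, ph, ph)
        np.testing.assert_array_equal(res.raw_scores, 0.0)

    def test_swapping_distance_matrices_negates_raw_scores(self):
        """DeltaD flips sign when the two module-distance matrices swap."""
        rng = np.random.default_rng(9)
        ph = ModulePartition(labels=np.array([0, 0, 0, 1, 1, 1]))
        pd_ = ModulePartition(labels=np.array([0, 0, 1, 1, 1, 0]))
        cells = self._cells(ph, pd_)
        dh = rng.uniform(0, 1, (6, cells.K))
        dd = rng.uniform(0, 1, (6, cells.K))
        fwd = netmoss_scores(dh, dd, cells, ph, pd_)
        rev = netmoss_scores(dd, dh, cells, ph, pd_)
        np.testing.assert_allclose(rev.raw_scores, -fwd.raw_scores, atol=1e-12)
        np.testing.assert_allclose(rev.delta_d, -fwd.delta_d, atol=1e-12)

    def test_single_cell_warns_and_zeroes(self):
        ph = ModulePartition(labels=np.zeros(5, dtype=int))
        cells = self._cells(ph, ph)
        with pytest.warns(UserWarning, match="single"):
            res = netmoss_scores(
                np.zeros((5, 1)), np.ones((5, 1)), cells, ph, ph
            )
        np.testing.assert_array_equal(res.scores, 0.0)

    def test_scores_min_max_normalized(self):
        rng = np.random.default_rng(10)
        ph = ModulePartition(labels=np.array([0, 0, 0, 1, 1, 1]))
        pd_ = ModulePartition(labels=np.array([0, 0, 1, 1, 1, 0]))
        cells = self._cells(ph, pd_)
        res = netmoss_scores(
            rng.uniform(0, 1, (6, cells.K)),
            rng.uniform(0, 1, (6, cells.K)),
            cells,
            ph,
            pd_,
        )
        assert res.scores.min() == 0.0
        assert res.scores.max() == 1.0


class TestRunNetmoss:
    def test_identical_groups_score_zero(self, small_spec):
        pair = simulate_pair(small_spec)
        net = pair.control_network()
        import warnings
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = run_netmoss_from_matrices(net, net, beta=6)
        np.testing.assert_array_equal(res.raw_scores, 0.0)

    def test_migrated_taxa_score_highest_among_disturbed(self):
        """Planted migrating submodules take the top normalized scores
        among the disturbed submodules (the benchmark's scored set)."""
        top_hits = []
        for seed in range(5):
            spec = SimulationSpec(seed=seed)
            pair = simulate_pair(spec)
            import warnings
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                res = run_netmoss_from_matrices(
                    pair.control_network(), pair.case_network(), beta=6
                )
            src = spec.module_indices()[spec.source_module]
            n_mig = len(pair.migrated)
            top = src[np.argsort(res.scores[src])[-n_mig:]]
            hits = len(set(top) & set(np.flatnonzero(pair.labels))) / n_mig
            top_hits.append(hits)
        assert np.mean(top_hits) >= 0.8

    def test_group_label_exchange_preserves_score_magnitudes(self, small_spec):
        """Exchanging group labels swaps the neighbor roles along with
        DeltaD's sign, so each node's driving-force magnitude is identical
        viewed from either direction of the transition."""
        pair = simulate_pair(small_spec)
        import warnings
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fwd = run_netmoss_from_matrices(
                pair.control_network(), pair.case_network(), beta=6
            )
            rev = run_netmoss_from_matrices(
                pair.case_network(), pair.control_network(), beta=6
            )
        np.testing.assert_allclose(
            np.abs(rev.raw_scores), np.abs(fwd.raw_scores), atol=1e-10
        )

    def test_full_pipeline_deterministic(self, small_spec):
        pair = simulate_pair(small_spec)
        import warnings
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            a = run_netmoss_from_matrices(pair.control_network(), pair.case_network(), beta=6)
            b = run_netmoss_from_matrices(pair.control_network(), pair.case_network(), beta=6)
        np.testing.assert_array_equal(a.scores, b.scores)
        np.testing.assert_array_equal(a.p_health.labels, b.p_health.labels)
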