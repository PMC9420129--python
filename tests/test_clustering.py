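"""Skeleton resampling, geodesic distances, and Monte Carlo null models."""

import itertools

import numpy as np
import pytest

from otomap.clustering import (
    ResampledSkeleton,
    observed_statistic,
    proximity_scores,
    resample_skeleton,
    run_null_model,
)
from otomap.core import Skeleton, ValidationError
from otomap.synthetic import generate_test_skeletons

from conftest import random_tree


def straight_cable(length=10.0, n=2):
    xs = np.linspace(0, length, n)
    return Skeleton(
        np.arange(n), np.arange(n) - 1, np.stack([xs, np.zeros(n), np.zeros(n)], axis=1)
    )


def y_tree():
    """5 um trunk with two 5 um branches."""
    return Skeleton(
        [0, 1, 2, 3],
        [-1, 0, 1, 1],
        [[0, 0, 0], [0, 0, 5], [0, 5, 5], [0, -5, 5]],
    )


def brute_force_geodesic(skel: Skeleton, ia: int, ib: int) -> float:
    """Independent oracle: BFS path search on the unweighted adjacency,
    then explicit Euclidean summation along the path."""
    adj = {k: [] for k in range(skel.n_nodes)}
    child, parent = skel.edges
    for c, p in zip(child, parent):
        adj[int(c)].append(int(p))
        adj[int(p)].append(int(c))
    prev = {ia: None}
    frontier = [ia]
    while frontier and ib not in prev:
        nxt = []
        for u in frontier:
            for v in adj[u]:
                if v not in prev:
                    prev[v] = u
                    nxt.append(v)
        frontier = nxt
    total, node = 0.0, ib
    while prev[node] is not None:
        total += float(np.linalg.norm(skel.xyz[node] - skel.xyz[prev[node]]))
        node = prev[node]
    return total


class TestResampling:
    def test_straight_cable_unit_spacing(self):
        rs = resample_skeleton(straight_cable(10.0), 1.0)
        assert rs.n_nodes == 11
        assert rs.edges[0].size == 10
        np.testing.assert_allclose(rs.edge_lengths, 1.0)
        assert rs.cable_length == pytest.approx(10.0)

    def test_y_tree_preserves_branch_point(self):
        rs = resample_skeleton(y_tree(), 1.0)
        assert rs.cable_length == pytest.approx(15.0, abs=0.15)
        # the branch point (0,0,5) survives exactly
        assert np.any(np.all(rs.xyz == [0, 0, 5], axis=1))
        n_children = np.bincount(
            rs.parent_index[rs.parent_index >= 0], minlength=rs.n_nodes
        )
        assert (n_children >= 2).sum() == 1

    @pytest.mark.parametrize("seed", range(10))
    def test_cable_length_conserved_on_random_arbors(self, seed):
        """Regularization preserves total cable within 1% on arbors with
        realistic curvature."""
        neurons, _ = generate_test_skeletons(n_neurons=1, seed=seed)
        skel = neurons[0][0]
        rs = resample_skeleton(skel, 1.0)
        assert rs.cable_length == pytest.approx(skel.cable_length, rel=0.01)
        assert np.all(rs.edge_lengths <= 1.5 * 1.0 + 1e-9)

    def test_jagged_tree_keeps_structure(self):
        """Even on a highly tortuous tree the resampled skeleton keeps the
        branch/leaf structure and the edge-spacing bound."""
        rng = np.random.default_rng(5)
        skel = random_tree(rng, 40, scale=3.0)
        rs = resample_skeleton(skel, 1.0)
        assert np.all(rs.edge_lengths <= 1.5 * 1.0 + 1e-9)

        def leaf_count(s):
            child, _ = s.edges
            has_child = np.zeros(s.n_nodes, bool)
            has_child[s.parent_index[s.parent_index >= 0]] = True
            return int((~has_child).sum())

        assert leaf_count(rs) == leaf_count(skel)

    def test_zero_spacing_rejected(self):
        with pytest.raises(ValidationError):
            resample_skeleton(straight_cable(), 0.0)

    def test_node_map_covers_original_ids(self):
        skel = straight_cable(10.0, n=6)
        rs = resample_skeleton(skel, 1.0)
        assert set(rs.node_map) == set(int(i) for i in skel.node_ids)


class TestGeodesics:
    def test_adjacent_nodes(self):
        skel = straight_cable(1.0)
        assert skel.geodesic_distance(0, 1) == pytest.approx(1.0)

    def test_y_tree_leaves(self):
        assert y_tree().geodesic_distance(2, 3) == pytest.approx(10.0)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force_on_random_trees(self, seed):
        rng = np.random.default_rng(100 + seed)
        skel = random_tree(rng, 50)
        D = skel.geodesic_matrix()
        for ia, ib in itertools.islice(
            itertools.combinations(range(50), 2), 0, None, 17
        ):
            assert D[ia, ib] == pytest.approx(
                brute_force_geodesic(skel, ia, ib), abs=1e-9
            )

    def test_metric_properties(self):
        rng = np.random.default_rng(3)
        skel = random_tree(rng, 30)
        D = skel.geodesic_matrix()
        np.testing.assert_allclose(D, D.T, atol=1e-12)
        assert np.all(np.diag(D) == 0)
        for _ in range(50):
            a, b, c = rng.integers(30, size=3)
            assert D[a, c] <= D[a, b] + D[b, c] + 1e-9


class TestObservedStatistic:
    def test_two_synapses_on_a_path(self):
        neurons = [(straight_cable(10.0), [[0, 0, 0], [10, 0, 0]])]
        overall, table = observed_statistic(neurons)
        assert overall == pytest.approx(10.0)
        assert table["n_synapses"].iloc[0] == 2

    def test_three_synapses_mean_pairwise(self):
        neurons = [(straight_cable(10.0), [[0, 0, 0], [5, 0, 0], [10, 0, 0]])]
        overall, _ = observed_statistic(neurons)
        assert overall == pytest.approx((5 + 10 + 5) / 3)

    def test_coincident_synapses_contribute_zero(self):
        neurons = [(straight_cable(10.0), [[0, 0, 0], [0, 0, 0], [10, 0, 0]])]
        overall, _ = observed_statistic(neurons)
        assert overall == pytest.approx((0 + 10 + 10) / 3)

    def test_single_synapse_neuron_excluded(self):
        neurons = [
            (straight_cable(10.0), [[0, 0, 0]]),
            (straight_cable(10.0), [[0, 0, 0], [10, 0, 0]]),
        ]
        with pytest.warns(UserWarning, match="fewer than two"):
            overall, table = observed_statistic(neurons)
        assert len(table) == 1

    def test_all_neurons_excluded_raises(self):
        with pytest.raises(ValidationError):
            with pytest.warns(UserWarning):
                observed_statistic([(straight_cable(), [[0, 0, 0]])])


class TestProximityScores:
    def test_radius_count_minus_one(self):
        skel = straight_cable(2.0, n=3)
        aff = [[0, 1, 0], [0, 2, 0], [0, 40, 0], [0, 100, 0]]
        s = proximity_scores(skel, aff, model="radius50")
        assert s[0] == 2.0  # 3 within 50 um, minus 1

    def test_linear_kernel(self):
        skel = straight_cable(2.0, n=3)
        s = proximity_scores(skel, [[0, 2.5, 0]], model="kernel5")
        assert s[0] == pytest.approx(0.5)  # 1 - 2.5/5

    def test_kernel_zero_beyond_halfwidth(self):
        skel = straight_cable(2.0, n=3)
        s = proximity_scores(skel, [[0, 7.0, 0]], model="kernel5")
        assert s[0] == 0.0

    def test_weighted_model_requires_afferents(self):
        with pytest.raises(ValidationError):
            proximity_scores(straight_cable(), None, model="kernel5")


class TestNullModel:
    def three_node_path(self):
        skel = straight_cable(2.0, n=3)
        return [(skel, np.array([[0.0, 0, 0], [2.0, 0, 0]]))]

    def exact_enumeration(self):
        """All 9 equiprobable with-replacement placements of 2 synapses on
        3 equidistant nodes."""
        dists = []
        for a, b in itertools.product(range(3), repeat=2):
            dists.append(abs(a - b) * 1.0)
        return np.mean(dists), np.std(dists)

    def test_unweighted_matches_exact_enumeration(self):
        mean, sd = self.exact_enumeration()
        assert mean == pytest.approx(8 / 9)
        res = run_null_model(self.three_node_path(), iterations=20_000, seed=5)
        se = sd / np.sqrt(res.iterations)
        assert abs(res.null_mean - mean) < 3 * se

    def test_reproducible_from_seed(self):
        a = run_null_model(self.three_node_path(), iterations=500, seed=9)
        b = run_null_model(self.three_node_path(), iterations=500, seed=9)
        np.testing.assert_array_equal(a.null_samples, b.null_samples)
        c = run_null_model(self.three_node_path(), iterations=500, seed=10)
        assert not np.array_equal(a.null_samples, c.null_samples)

    def test_rigid_motion_invariance(self):
        """Null distributions do not change under rotation + translation."""
        neurons, _ = generate_test_skeletons(n_neurons=2, seed=1)
        res_a = run_null_model(neurons, iterations=400, seed=2)
        theta = 0.7
        R = np.array(
            [[np.cos(theta), -np.sin(theta), 0],
             [np.sin(theta), np.cos(theta), 0],
             [0, 0, 1]]
        )
        moved = []
        for skel, syn in neurons:
            sk2 = Skeleton(
                skel.node_ids,
                np.where(skel.parent_index < 0, -1, skel.node_ids[skel.parent_index]),
                skel.xyz @ R.T + 5.0, skel.radius, label=skel.label,
            )
            moved.append((sk2, np.asarray(syn) @ R.T + 5.0))
        res_b = run_null_model(moved, iterations=400, seed=2)
        np.testing.assert_allclose(res_b.null_samples, res_a.null_samples, atol=1e-6)
        assert res_b.observed == pytest.approx(res_a.observed, abs=1e-6)

    def test_ci_brackets_mean_and_p_in_range(self):
        res = run_null_model(self.three_node_path(), iterations=1000, seed=0)
        assert res.ci_low <= res.null_mean <= res.ci_high
        assert 1 / (res.iterations + 1) <= res.empirical_p <= 1.0

    def test_all_zero_scores_fall_back_to_uniform(self):
        skel = straight_cable(10.0)
        neurons = [(skel, [[0, 0, 0], [10, 0, 0]])]
        far_afferent = np.array([[0.0, 1000.0, 0.0]])
        res = run_null_model(
            neurons, far_afferent, model="kernel5", iterations=200, seed=1
        )
        assert res.uniform_fallback == ["0"] or len(res.uniform_fallback) == 1

    def test_planted_scale_orders_p_values(self):
        """Tighter planted clustering gives smaller empirical p."""
        ps = {}
        for scale in (2.0, 20.0):
            p_vals = []
            for rep in range(5):
                neurons, aff = generate_test_skeletons(
                    n_neurons=8, placement="clustered", cluster_scale=scale,
                    seed=300 + rep,
                )
                p_vals.append(
                    run_null_model(neurons, iterations=800, seed=rep).empirical_p
                )
            ps[scale] = np.mean(p_vals)
        assert ps[2.0] < ps[20.0]

    def test_without_replacement_mode(self):
        neurons, _ = generate_test_skeletons(n_neurons=1, seed=4)
        res = run_null_model(
            neurons, iterations=300, seed=3, with_replacement=False
        )
        assert res.ci_low <= res.ci_high
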