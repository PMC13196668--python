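"""KNN weights graph, join counts, permutation null, KDE maps."""

import itertools

import numpy as np
import pytest

from utriclemap.geometry import normalize_organ
from utriclemap.quantify import classify_cells
from utriclemap.simulate import SimParams, generate_dataset
from utriclemap.spatial import (
    join_counts,
    kde_map,
    knn_graph,
    permutation_null,
)


@pytest.fixture(scope="module")
def small_graph():
    """Fixed 6-node graph with an exhaustively enumerable labeling null."""
    pts = np.random.default_rng(1).normal(size=(6, 2))
    return knn_graph(pts, k=2)


class TestKnnGraph:
    def test_k_equals_n_minus_one_forces_complete_graph(self):
        pts = np.random.default_rng(0).normal(size=(8, 2))
        g = knn_graph(pts, k=7)
        assert g.n_edges == 28

    def test_collinear_k1_gives_path(self):
        pts = np.column_stack([np.arange(5.0), np.zeros(5)])
        g = knn_graph(pts, k=1)
        assert g.edges == ((0, 1), (1, 2), (2, 3), (3, 4))

    def test_adjacency_symmetric_without_self_edges(self):
        pts = np.random.default_rng(2).normal(size=(40, 2))
        g = knn_graph(pts, k=5)
        assert all(u < v for u, v in g.edges)
        assert (g.degrees >= 5).all()

    def test_too_few_points_error_names_minimum(self):
        with pytest.raises(ValueError, match="minimum n = 8"):
            knn_graph(np.zeros((7, 2)), k=7)

    def test_k7_leaves_no_unattached_cells_on_synthetic_organs(self):
        for seed in range(5):
            table, _ = generate_dataset(SimParams(n_cells=60, seed=seed))
            g = knn_graph(table[["x", "y"]].to_numpy(), k=7)
            assert (g.degrees > 0).all()


class TestJoinCounts:
    def test_uniform_labels_put_all_joins_on_diagonal(self, small_graph):
        res = join_counts(np.array(["A"] * 6), small_graph)
        assert res.observed[("A", "A")] == small_graph.n_edges

    def test_alternating_path(self):
        pts = np.column_stack([np.arange(4.0), np.zeros(4)])
        g = knn_graph(pts, k=1)
        res = join_counts(np.array(list("ABAB")), g)
        assert res.observed == {("A", "A"): 0, ("A", "B"): 3, ("B", "B"): 0}

    def test_label_length_mismatch_rejected(self, small_graph):
        with pytest.raises(ValueError):
            join_counts(np.array(["A", "B"]), small_graph)

    def test_conservation_on_random_graphs(self):
        """Sum of pairwise joins equals |E| for arbitrary labelings."""
        rng = np.random.default_rng(0)
        for _ in range(100):
            n = int(rng.integers(8, 40))
            pts = rng.normal(size=(n, 2))
            g = knn_graph(pts, k=int(rng.integers(1, 6)))
            labels = rng.choice(list("ABC"), size=n)
            res = join_counts(labels, g)
            assert sum(res.observed.values()) == g.n_edges


class TestPermutationNull:
    def test_seed_determinism(self, small_graph):
        labels = np.array(list("AAABBB"))
        a = permutation_null(labels, small_graph, n_perm=999, seed=5)
        b = permutation_null(labels, small_graph, n_perm=999, seed=5)
        assert a.pseudo_p == b.pseudo_p

    def test_constant_labels_give_degenerate_null(self, small_graph):
        res = permutation_null(np.array(["A"] * 6), small_graph, n_perm=99, seed=0)
        assert res.pseudo_p[("A", "A")] == 1.0
        assert res.null_sd[("A", "A")] == 0.0

    def test_pseudo_p_floor_is_add_one(self, small_graph):
        labels = np.array(list("AAABBB"))
        res = permutation_null(labels, small_graph, n_perm=9999, seed=1)
        assert all(p >= 1 / 10000 for p in res.pseudo_p.values())

    def test_matches_exhaustive_enumeration_on_six_nodes(self, small_graph):
        """Sampled pseudo-p vs the exact tail over all 20 assignments of
        3 A's and 3 B's, within 3 binomial SEs at 9999 permutations."""
        labels = np.array(list("AAABBB"))
        obs = join_counts(labels, small_graph).observed[("A", "B")]
        tails = []
        for pos in itertools.combinations(range(6), 3):
            lab = np.array(["B"] * 6)
            lab[list(pos)] = "A"
            tails.append(join_counts(lab, small_graph).observed[("A", "B")] >= obs)
        exact = np.mean(tails)
        res = permutation_null(labels, small_graph, n_perm=9999, seed=3)
        se = np.sqrt(exact * (1 - exact) / 9999)
        assert abs(res.pseudo_p[("A", "B")] - exact) <= 3 * se + 1e-4

    def test_super_uniform_under_random_labels(self):
        """Permutation exchangeability: rejection rate at alpha=0.05 over
        500 random-label datasets stays at or below 6.5%."""
        rng = np.random.default_rng(7)
        rejections = 0
        pts = rng.normal(size=(40, 2))
        g = knn_graph(pts, k=7)
        for i in range(500):
            labels = rng.choice(["A", "B"], size=40)
            if len(np.unique(labels)) < 2:
                continue
            res = permutation_null(labels, g, n_perm=199, seed=int(rng.integers(2**31)))
            rejections += res.pseudo_p[("A", "A")] < 0.05
        assert rejections / 500 <= 0.065

    def test_invalid_n_perm_rejected(self, small_graph):
        with pytest.raises(ValueError):
            permutation_null(np.array(list("AAABBB")), small_graph, n_perm=0, seed=0)


class TestKdeMap:
    def test_tight_cluster_peaks_at_cluster(self):
        rng = np.random.default_rng(0)
        theta = np.full(60, 315.0) + rng.normal(0, 2, 60)
        r = np.clip(np.full(60, np.sqrt(0.5)) + rng.normal(0, 0.02, 60), 0, 1)
        grid = kde_map(theta, r, grid_n=101)
        i, j = np.unravel_index(np.argmax(grid.density), grid.density.shape)
        cell = grid.x[1] - grid.x[0]
        assert abs(grid.x[j] - 0.5) <= 2 * cell
        assert abs(grid.y[i] - (-0.5)) <= 2 * cell

    def test_two_separated_clusters_give_two_modes(self):
        rng = np.random.default_rng(1)
        theta = np.concatenate([np.zeros(50), np.full(50, 180.0)]) + rng.normal(0, 4, 100)
        r = np.clip(0.6 + rng.normal(0, 0.03, 100), 0, 1)
        grid = kde_map(theta, r, grid_n=101)
        mid = len(grid.x) // 2
        left = grid.density[:, :mid].max()
        right = grid.density[:, mid:].max()
        trough = grid.density[:, mid - 2 : mid + 3].max()
        assert left > 2 * trough and right > 2 * trough

    def test_density_nonnegative_and_normalized(self):
        rng = np.random.default_rng(2)
        theta = rng.uniform(0, 360, 200)
        r = np.sqrt(rng.uniform(0, 1, 200))
        grid = kde_map(theta, r, grid_n=141, extent=2.0)
        assert (grid.density >= 0).all()
        assert grid.integral() == pytest.approx(1.0, abs=0.01)

    def test_degenerate_input_rejected(self):
        with pytest.raises(ValueError):
            kde_map([45.0] * 5, [0.5] * 5)
        with pytest.raises(ValueError):
            kde_map([45.0], [0.5])
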