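"""Adaptive rewiring: pivot/candidate selection and trajectory invariants."""

import numpy as np
import pytest
from scipy.linalg import expm
from scipy.stats import chisquare

from heatrewire import (
    RewiringConfig,
    RewiringImpossibleError,
    WeightedGraph,
    normalized_laplacian,
    run_rewiring,
)
from heatrewire.rewiring import (
    diffusion_candidates,
    random_candidates,
    rewire_step,
    select_pivot,
)

from conftest import random_weighted_graph


def star(n: int) -> WeightedGraph:
    A = np.zeros((n, n))
    A[0, 1:] = 1.0
    A[1:, 0] = 1.0
    return WeightedGraph(A)


class TestSelectPivot:
    def test_star_hub_excluded(self):
        rng = np.random.default_rng(0)
        picks = {select_pivot(star(4), rng) for _ in range(200)}
        assert picks == {1, 2, 3}  # hub has degree n-1

    def test_isolated_node_excluded(self):
        A = np.zeros((3, 3))
        A[0, 1] = A[1, 0] = 1.0
        rng = np.random.default_rng(1)
        picks = {select_pivot(WeightedGraph(A), rng) for _ in range(100)}
        assert 2 not in picks

    def test_uniform_over_eligible_nodes(self, path4):
        # on the 4-node path every node has 0 < d < n-1, so each should be
        # picked with probability 1/4
        rng = np.random.default_rng(2)
        counts = np.bincount(
            [select_pivot(path4, rng) for _ in range(10000)], minlength=4
        )
        assert chisquare(counts).pvalue > 0.01

    def test_complete_graph_signals_impossible(self, triangle):
        with pytest.raises(RewiringImpossibleError):
            select_pivot(triangle, np.random.default_rng(0))


class TestDiffusionCandidates:
    def test_path_pivot_zero_prefers_nearer_non_neighbor(self, path4):
        # brute-force oracle: full matrix exponential of the 4-node path
        H = expm(-1.0 * normalized_laplacian(path4))
        assert H[0, 2] > H[0, 3]  # heat reaches node 2 before node 3
        rng = np.random.default_rng(0)
        j1, j2 = diffusion_candidates(path4, 1.0, 0, rng)
        assert (j1, j2) == (2, 1)

    def test_single_neighbor_is_always_pruned(self, path4):
        for tau in (0.5, 3.0, 8.0):
            _, j2 = diffusion_candidates(path4, tau, 0, np.random.default_rng(1))
            assert j2 == 1

    def test_automorphic_tie_broken_uniformly(self):
        # path 1-0-2 plus isolated nodes 3, 4: nodes 3 and 4 are automorphic
        # non-neighbors of 0 receiving identical (zero) heat
        A = np.zeros((5, 5))
        A[0, 1] = A[1, 0] = A[0, 2] = A[2, 0] = 1.0
        G = WeightedGraph(A)
        rng = np.random.default_rng(3)
        picks = np.array([diffusion_candidates(G, 1.0, 1, rng)[0] for _ in range(400)])
        # non-neighbors of node 1 are {2 reachable, 3, 4 isolated}; node 2
        # gets real heat so j1 == 2 always... instead check pivot 0 pruning tie
        assert set(picks) == {2}
        prunes = np.array([diffusion_candidates(G, 1.0, 0, rng)[1] for _ in range(400)])
        frac = np.mean(prunes == 1)
        assert set(prunes) == {1, 2}
        assert 0.4 < frac < 0.6

    def test_candidates_respect_adjacency(self):
        G = random_weighted_graph(12, 0.4, 5)
        rng = np.random.default_rng(6)
        k = select_pivot(G, rng)
        j1, j2 = diffusion_candidates(G, 2.0, k, rng)
        assert G.adjacency[k, j1] == 0 and j1 != k
        assert G.adjacency[k, j2] > 0


class TestRandomCandidates:
    def test_forced_pair(self):
        # node 0 on a 3-node path: one neighbor (1), one non-neighbor (2)
        A = np.zeros((3, 3))
        A[0, 1] = A[1, 0] = A[1, 2] = A[2, 1] = 1.0
        G = WeightedGraph(A)
        j1, j2 = random_candidates(G, 0, np.random.default_rng(0))
        assert (j1, j2) == (2, 1)

    def test_uniformity_over_candidate_sets(self):
        G = random_weighted_graph(6, 0.5, 8)
        k = 0
        neighbors = np.flatnonzero(G.adjacency[k] > 0)
        non_neighbors = np.flatnonzero(
            (G.adjacency[k] == 0) & (np.arange(6) != k)
        )
        assert len(neighbors) >= 2 and len(non_neighbors) >= 2
        rng = np.random.default_rng(9)
        draws = [random_candidates(G, k, rng) for _ in range(10000)]
        j1s = np.array([d[0] for d in draws])
        j2s = np.array([d[1] for d in draws])
        assert set(j1s) == set(non_neighbors.tolist())
        assert set(j2s) == set(neighbors.tolist())
        c1 = np.array([(j1s == j).sum() for j in non_neighbors])
        c2 = np.array([(j2s == j).sum() for j in neighbors])
        assert chisquare(c1).pvalue > 0.01
        assert chisquare(c2).pvalue > 0.01


class TestRewireStep:
    def test_weight_multiset_and_degrees_bookkeeping(self, path4):
        cfg = RewiringConfig(tau=1.0, p_random=0.0, steps=1)
        rng = np.random.default_rng(0)
        G1 = rewire_step(path4, cfg, rng)
        assert G1.edge_count == path4.edge_count
        w0 = np.sort(path4.edges()[2])
        w1 = np.sort(G1.edges()[2])
        np.testing.assert_allclose(w0, w1)

    def test_deterministic_diffusion_step_on_path(self, path4):
        # force pivot 0 by making the middle nodes full-degree ineligible:
        # instead run until the known (k=0) step occurs; simpler: check the
        # edge move directly with pivot 0 via the candidate functions
        rng = np.random.default_rng(0)
        j1, j2 = diffusion_candidates(path4, 1.0, 0, rng)
        A = path4.adjacency.copy()
        w = A[0, j2]
        A[0, j2] = A[j2, 0] = 0.0
        A[0, j1] = A[j1, 0] = w
        G1 = WeightedGraph(A)
        # edge (0,1) replaced by (0,2) carrying weight 1
        assert G1.adjacency[0, 1] == 0.0
        assert G1.adjacency[0, 2] == 1.0

    def test_pivot_degree_conserved_neighbors_shift(self):
        G = random_weighted_graph(10, 0.4, 3)
        cfg = RewiringConfig(tau=2.0, p_random=0.0, steps=1)
        d0 = G.degrees.copy()
        G1 = rewire_step(G, cfg, np.random.default_rng(4))
        d1 = G1.degrees
        diff = d1 - d0
        assert sorted(diff.tolist()) == [-1] + [0] * (G.n - 2) + [1]


class TestRunRewiring:
    def test_zero_steps_returns_input(self, path4):
        res = run_rewiring(path4, RewiringConfig(tau=1.0, steps=0, seed=0))
        assert res.completed
        np.testing.assert_array_equal(res.graph.adjacency, path4.adjacency)

    def test_trajectory_deterministic(self):
        G = random_weighted_graph(20, 0.3, 1)
        cfg = RewiringConfig(tau=2.0, p_random=0.2, steps=100, seed=5)
        A1 = run_rewiring(G, cfg).graph.adjacency
        A2 = run_rewiring(G, cfg).graph.adjacency
        np.testing.assert_array_equal(A1, A2)

    def test_conservation_along_long_trajectory(self):
        G = random_weighted_graph(25, 0.3, 2)
        cfg = RewiringConfig(tau=3.0, p_random=0.2, steps=2000, seed=6)
        res = run_rewiring(G, cfg)
        final = res.graph
        assert final.edge_count == G.edge_count
        np.testing.assert_allclose(
            np.sort(final.edges()[2]), np.sort(G.edges()[2]), atol=1e-12
        )
        np.testing.assert_allclose(final.adjacency, final.adjacency.T, atol=0)
        assert np.all(np.diagonal(final.adjacency) == 0)

    def test_diffusion_candidates_are_extremal_along_trajectory(self):
        # at every step of a trajectory, j1/j2 must be the argmax over
        # non-neighbors / argmin over neighbors of the full-kernel row
        # (independent spectral evaluation)
        from heatrewire.graph import heat_kernel

        G = random_weighted_graph(12, 0.4, 7)
        tau = 2.0
        rng = np.random.default_rng(8)
        for _ in range(20):
            k = select_pivot(G, rng)
            j1, j2 = diffusion_candidates(G, tau, k, rng)
            H = heat_kernel(G, tau).matrix
            A = G.adjacency
            non_nb = np.flatnonzero((A[k] == 0) & (np.arange(G.n) != k))
            nb = np.flatnonzero(A[k] > 0)
            assert H[k, j1] >= H[k, non_nb].max() - 1e-10
            assert H[k, j2] <= H[k, nb].min() + 1e-10
            w = A[k, j2]
            A[k, j2] = A[j2, k] = 0.0
            A[k, j1] = A[j1, k] = w

    def test_snapshots_recorded_at_cadence(self):
        G = random_weighted_graph(15, 0.4, 9)
        cfg = RewiringConfig(tau=1.5, p_random=0.2, steps=50, seed=10)
        res = run_rewiring(G, cfg, snapshot_every=20)
        assert [s for s, _ in res.snapshots] == [20, 40]
        assert res.snapshots[0][1].edge_count == G.edge_count

    def test_config_validation(self):
        with pytest.raises(ValueError):
            RewiringConfig(tau=0.0)
        with pytest.raises(ValueError):
            RewiringConfig(tau=1.0, p_random=1.5)
        with pytest.raises(ValueError):
            RewiringConfig(tau=1.0, steps=-1)
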