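import itertools

import numpy as np
import pytest
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import dijkstra

from poptraj.errors import TrajectoryError
from poptraj.graph import Edge, PopulationGraph
from poptraj.trajectory import (
    Trajectory,
    assign_pseudotime,
    detect_trajectories,
    floyd_warshall,
    project_cell,
    reconstruct_path,
)

from conftest import chain_populations


def graph_from_edges(n, edges):
    """PopulationGraph on nodes 0..n-1 from (s, q, w) triples."""
    return PopulationGraph(
        pop_ids=list(range(n)),
        edges=[Edge(s, q, 0.5, 0.5, w) for s, q, w in edges],
        k=0, lam=3.0, beta=1.0,
    )


def brute_force_shortest(n, edges, s, q):
    """Exhaustive minimum over all simple paths (oracle for small graphs)."""
    w = {(a, b): c for a, b, c in edges}
    best = np.inf
    for r in range(n):
        for mid in itertools.permutations([v for v in range(n) if v not in (s, q)], r):
            path = (s, *mid, q)
            cost = 0.0
            ok = True
            for a, b in zip(path, path[1:]):
                if (a, b) not in w:
                    ok = False
                    break
                cost += w[(a, b)]
            if ok:
                best = min(best, cost)
    return best


class TestFloydWarshall:
    def test_simple_chain(self):
        g = graph_from_edges(3, [(0, 1, 1.0), (1, 2, 1.0)])
        dist, nxt = floyd_warshall(g)
        assert dist[0, 2] == pytest.approx(2.0)
        assert reconstruct_path(g, nxt, 0, 2) == [0, 1, 2]

    def test_unreachable_pair_is_infinite(self):
        g = graph_from_edges(3, [(0, 1, 1.0)])
        dist, nxt = floyd_warshall(g)
        assert np.isinf(dist[1, 0]) and np.isinf(dist[2, 0])
        with pytest.raises(TrajectoryError):
            reconstruct_path(g, nxt, 2, 0)

    def test_negative_edge_shortcut_matches_enumeration(self):
        edges = [(0, 1, 2.0), (1, 2, 2.0), (0, 2, 5.0), (2, 3, 1.0), (1, 3, -0.5)]
        g = graph_from_edges(4, edges)
        dist, _ = floyd_warshall(g)
        for s in range(4):
            for q in range(4):
                if s != q:
                    assert dist[s, q] == pytest.approx(
                        brute_force_shortest(4, edges, s, q)
                    )

    def test_matches_dijkstra_on_random_positive_digraphs(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            n = int(rng.integers(4, 9))
            mask = rng.random((n, n)) < 0.4
            np.fill_diagonal(mask, False)
            W = np.where(mask, rng.uniform(0.1, 2.0, size=(n, n)), 0.0)
            edges = [(i, j, W[i, j]) for i in range(n) for j in range(n) if mask[i, j]]
            dist, _ = floyd_warshall(graph_from_edges(n, edges))
            ref = dijkstra(csr_matrix(W))
            np.testing.assert_allclose(dist, ref, atol=1e-10)

    def test_triangle_inequality_after_completion(self):
        rng = np.random.default_rng(1)
        n = 7
        edges = [
            (i, j, float(rng.uniform(0.1, 2)))
            for i in range(n) for j in range(n)
            if i != j and rng.random() < 0.5
        ]
        dist, _ = floyd_warshall(graph_from_edges(n, edges))
        for s, o, q in itertools.product(range(n), repeat=3):
            assert dist[s, q] <= dist[s, o] + dist[o, q] + 1e-12

    def test_negative_cycle_detected(self):
        g = graph_from_edges(2, [(0, 1, 1.0), (1, 0, -2.0)])
        with pytest.raises(TrajectoryError, match="negative cycle"):
            floyd_warshall(g)


class TestDetectTrajectories:
    def test_forward_chain_yields_single_full_path(self):
        g = graph_from_edges(4, [(0, 1, 1.0), (1, 2, 1.0), (2, 3, 1.0)])
        dist, nxt = floyd_warshall(g)
        trajs = detect_trajectories(g, dist, nxt)
        assert len(trajs) == 1
        assert trajs[0].pop_sequence == [0, 1, 2, 3]

    def test_bifurcation_yields_two_paths_sharing_trunk(self):
        edges = [(0, 1, 1.0), (1, 2, 1.0), (1, 3, 1.0)]
        g = graph_from_edges(4, edges)
        dist, nxt = floyd_warshall(g)
        trajs = detect_trajectories(g, dist, nxt)
        assert len(trajs) == 2
        seqs = sorted(tuple(t.pop_sequence) for t in trajs)
        assert seqs == [(0, 1, 2), (0, 1, 3)]
        # trunk pops are assigned to the first path only
        assert set(trajs[0].assigned_pops) & set(trajs[1].assigned_pops) == set()

    def test_max_paths_one_takes_best_coverage(self):
        edges = [(0, 1, 1.0), (1, 2, 1.0), (2, 3, 1.0), (1, 4, 1.0)]
        g = graph_from_edges(5, edges)
        dist, nxt = floyd_warshall(g)
        trajs = detect_trajectories(g, dist, nxt, max_paths=1)
        assert len(trajs) == 1
        assert trajs[0].pop_sequence == [0, 1, 2, 3]  # covers 4 pops, not 3

    def test_empty_graph_rejected(self):
        g = PopulationGraph(pop_ids=[], edges=[], k=0, lam=3.0, beta=1.0)
        with pytest.raises(TrajectoryError):
            detect_trajectories(g, np.zeros((0, 0)), np.zeros((0, 0), dtype=int))


class TestProjection:
    def test_cell_at_centroid_projects_to_centroid(self):
        cp = chain_populations([[1.0, 2.0]], [[1.0, 0.0]], [[0]])[0]
        xhat, delta = project_cell([1.0, 2.0], cp)
        np.testing.assert_allclose(xhat, [1.0, 2.0])
        assert delta == 0.0

    def test_unit_step_along_velocity(self):
        cp = chain_populations([[0.0, 0.0]], [[3.0, 4.0]], [[0]])[0]
        _, delta = project_cell([3.0, 4.0], cp)
        assert delta == pytest.approx(1.0)

    def test_orthogonal_component_discarded(self):
        cp = chain_populations([[0.0, 0.0]], [[1.0, 0.0]], [[0]])[0]
        xhat, delta = project_cell([2.0, 5.0], cp)
        np.testing.assert_allclose(xhat, [2.0, 0.0])
        assert delta == pytest.approx(2.0)

    def test_zero_velocity_rejected(self):
        cp = chain_populations([[0.0]], [[0.0]], [[0]])[0]
        with pytest.raises(TrajectoryError):
            project_cell([1.0], cp)


class TestPseudotime:
    def test_cells_at_centroids_get_rescaled_pop_positions(self):
        X = np.array([[0.0], [5.0], [10.0]])
        pops = chain_populations([[0.0], [5.0], [10.0]], [[1.0]] * 3, [[0], [1], [2]])
        traj = Trajectory(path_id=0, pop_sequence=[0, 1, 2], assigned_pops=[0, 1, 2])
        assign_pseudotime(traj, pops, X)
        np.testing.assert_allclose(
            [traj.cell_times[i] for i in range(3)], [0.0, 0.5, 1.0]
        )

    def test_six_cell_chain_hand_computed(self):
        # 3 CPs at 0/10/20 with v=1; cells at centroid +/- 1 -> delta = +/-1,
        # rescaled to +/-0.45; raw times [-0.45, .45, .55, 1.45, 1.55, 2.45]
        X = np.array([[-1.0], [1.0], [9.0], [11.0], [19.0], [21.0]])
        pops = chain_populations(
            [[0.0], [10.0], [20.0]], [[1.0]] * 3, [[0, 1], [2, 3], [4, 5]]
        )
        traj = Trajectory(path_id=0, pop_sequence=[0, 1, 2], assigned_pops=[0, 1, 2])
        assign_pseudotime(traj, pops, X)
        raw = np.array([-0.45, 0.45, 0.55, 1.45, 1.55, 2.45])
        expected = (raw - raw.min()) / (raw.max() - raw.min())
        got = np.array([traj.cell_times[i] for i in range(6)])
        np.testing.assert_allclose(got, expected, atol=1e-12)
        np.testing.assert_allclose(
            [traj.cell_times_raw[i] for i in range(6)], raw, atol=1e-12
        )

    def test_within_cp_order_preserved(self):
        X = np.array([[-2.0], [3.0]])
        pops = chain_populations([[0.0]], [[1.0]], [[0, 1]])
        traj = Trajectory(path_id=0, pop_sequence=[0], assigned_pops=[0])
        assign_pseudotime(traj, pops, X)
        assert traj.cell_times[0] < traj.cell_times[1]
        assert traj.cell_times[0] == 0.0 and traj.cell_times[1] == 1.0

    def test_single_cell_path_gets_zero_by_convention(self):
        X = np.array([[1.0]])
        pops = chain_populations([[0.0]], [[1.0]], [[0]])
        traj = Trajectory(path_id=0, pop_sequence=[0], assigned_pops=[0])
        assign_pseudotime(traj, pops, X)
        assert traj.cell_times == {0: 0.0}

    def test_normalized_times_always_in_unit_interval(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(30, 2)) * 5
        pops = chain_populations(
            [X[:10].mean(0), X[10:20].mean(0), X[20:].mean(0)],
            [rng.normal(size=2) for _ in range(3)],
            [range(10), range(10, 20), range(20, 30)],
        )
        traj = Trajectory(path_id=0, pop_sequence=[0, 1, 2], assigned_pops=[0, 1, 2])
        assign_pseudotime(traj, pops, X)
        vals = np.array(list(traj.cell_times.values()))
        assert vals.min() == 0.0 and vals.max() == 1.0
        assert ((vals >= 0) & (vals <= 1)).all()
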