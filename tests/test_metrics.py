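import networkx as nx
import numpy as np
import pytest
from scipy.sparse.csgraph import floyd_warshall

from costnet.connectivity import BinaryNetwork, CorrelationMatrix
from costnet.metrics import (
    cost_efficiency,
    efficiency_curves,
    global_efficiency,
    lattice_reference,
    local_efficiency,
    random_reference,
    shortest_path_lengths,
    small_world_cost_range,
    smooth_and_peak,
)


def net_from_edges(n, edges, cost=None):
    names = [f"n{i}" for i in range(n)]
    adj = np.zeros((n, n), dtype=bool)
    for i, j in edges:
        adj[i, j] = adj[j, i] = True
    n_pairs = n * (n - 1) / 2
    return BinaryNetwork(
        names, adj, cost=len(edges) / n_pairs if cost is None else cost
    )


def random_net(rng, n, p=0.3):
    iu = np.triu_indices(n, 1)
    adj = np.zeros((n, n), dtype=bool)
    mask = rng.random(iu[0].size) < p
    adj[iu[0][mask], iu[1][mask]] = True
    adj |= adj.T
    return BinaryNetwork([f"n{i}" for i in range(n)], adj, cost=float(mask.mean()))


class TestShortestPaths:
    def test_path_graph_distances(self):
        net = net_from_edges(3, [(0, 1), (1, 2)])
        d = shortest_path_lengths(net)
        assert d.loc["n0", "n2"] == 2
        assert d.loc["n0", "n1"] == 1

    def test_disconnected_pair_is_nan(self):
        net = net_from_edges(3, [(0, 1)])
        d = shortest_path_lengths(net)
        assert np.isnan(d.loc["n0", "n2"])

    def test_matches_floyd_warshall_oracle(self, rng):
        net = random_net(rng, 20)
        ours = shortest_path_lengths(net).to_numpy()
        oracle = floyd_warshall(net.adjacency.astype(float), unweighted=True)
        oracle[np.isinf(oracle)] = np.nan
        np.testing.assert_array_equal(np.isnan(ours), np.isnan(oracle))
        assert np.allclose(
            ours[~np.isnan(ours)], oracle[~np.isnan(oracle)]
        )


class TestEfficiencies:
    def test_complete_and_empty_graph(self):
        assert global_efficiency(net_from_edges(4, [(0, 1), (0, 2), (0, 3), (1, 2), (1, 3), (2, 3)])) == 1.0
        assert global_efficiency(net_from_edges(4, [])) == 0.0
        assert local_efficiency(net_from_edges(4, [])) == 0.0

    def test_path_graph_global_efficiency(self):
        # P3: pair inverses 1 + 1 + 1/2 over 3 unordered pairs -> 5/6
        assert global_efficiency(net_from_edges(3, [(0, 1), (1, 2)])) == pytest.approx(5 / 6)

    def test_triangle_and_square_local_efficiency(self):
        assert local_efficiency(net_from_edges(3, [(0, 1), (1, 2), (0, 2)])) == pytest.approx(1.0)
        assert local_efficiency(net_from_edges(4, [(0, 1), (1, 2), (2, 3), (3, 0)])) == 0.0

    def test_cost_efficiency_of_path_graph(self):
        net = net_from_edges(3, [(0, 1), (1, 2)], cost=2 / 3)
        assert cost_efficiency(net) == pytest.approx(5 / 6 - 2 / 3)

    def test_matches_networkx_on_random_graphs(self, rng):
        for _ in range(10):
            net = random_net(rng, 12, p=0.35)
            g = net.to_networkx()
            assert global_efficiency(net) == pytest.approx(
                nx.global_efficiency(g), abs=1e-12
            )
            assert local_efficiency(net) == pytest.approx(
                nx.local_efficiency(g), abs=1e-12
            )

    def test_monotone_under_edge_addition(self, rng):
        net = random_net(rng, 10, p=0.2)
        e = global_efficiency(net)
        adj = net.adjacency.copy()
        free = np.argwhere(~adj & ~np.eye(10, dtype=bool))
        i, j = free[rng.integers(len(free))]
        adj[i, j] = adj[j, i] = True
        denser = BinaryNetwork(net.names, adj, cost=net.cost)
        assert global_efficiency(denser) >= e


class TestNullModels:
    def test_swap_preserves_degree_sequence(self, rng):
        for _ in range(5):
            net = random_net(rng, 15, p=0.3)
            ref = random_reference(net, seed=int(rng.integers(2**31)))
            np.testing.assert_array_equal(
                ref.degree_sequence(), net.degree_sequence()
            )
            assert ref.n_edges == net.n_edges

    def test_star_graph_has_no_valid_swaps(self):
        net = net_from_edges(5, [(0, i) for i in range(1, 5)])
        ref = random_reference(net, seed=0)
        assert ref.edge_set() == net.edge_set()
        assert ref.swap_failures > 0

    def test_deterministic_for_fixed_seed(self, rng):
        net = random_net(rng, 12, p=0.4)
        a = random_reference(net, seed=99)
        b = random_reference(net, seed=99)
        np.testing.assert_array_equal(a.adjacency, b.adjacency)

    def test_ring_lattice_shapes(self):
        c6 = lattice_reference(6, 6)
        assert sorted(map(tuple, np.argwhere(np.triu(c6.adjacency)))) == [
            (0, 1), (0, 5), (1, 2), (2, 3), (3, 4), (4, 5),
        ]
        assert global_efficiency(c6) == pytest.approx(2 / 3)

        c5 = lattice_reference(5, 5)
        assert all(d == 2 for d in c5.degree_sequence())

        complete = lattice_reference(5, 10)
        assert global_efficiency(complete) == 1.0

    def test_lattice_rejects_too_many_edges(self):
        with pytest.raises(ValueError):
            lattice_reference(4, 7)


def small_world_corr(rng, n=24, k=6, p=0.15):
    """Correlation matrix whose strongest entries trace a Watts-Strogatz
    graph: clustered lattice neighbourhoods with a few random shortcuts, the
    canonical small-world structure."""
    g = nx.watts_strogatz_graph(n, k, p, seed=int(rng.integers(2**31)))
    r = rng.uniform(0.0, 0.3, size=(n, n))
    for i, j in g.edges:
        r[i, j] = 0.5 + rng.uniform(0.0, 0.2)
    r = np.triu(r, 1)
    r = r + r.T
    np.fill_diagonal(r, 1.0)
    return CorrelationMatrix([f"n{i}" for i in range(n)], r, 400)


def noise_corr(rng, n=24, frames=400):
    data = rng.normal(size=(frames, n))
    r = np.corrcoef(data, rowvar=False)
    np.fill_diagonal(r, 1.0)
    return CorrelationMatrix([f"n{i}" for i in range(n)], r, frames)


class TestCurvesAndSmallWorld:
    def test_full_cost_endpoint(self, rng):
        corr = noise_corr(rng, n=10)
        curve = efficiency_curves(corr, cost_grid=[0.5, 1.0], n_null=3, seed=0)
        end = curve.table.iloc[-1]
        assert end["e_glob"] == 1.0
        assert end["ce"] == pytest.approx(0.0)
        assert end["e_glob_rand"] == 1.0
        assert end["e_glob_latt"] == 1.0

    def test_clustered_matrix_is_small_world_but_noise_is_not(self, rng):
        grid = np.round(np.arange(0.10, 0.45, 0.05), 3)
        clustered = efficiency_curves(
            small_world_corr(rng), cost_grid=grid, n_null=8, seed=1
        )
        sw = small_world_cost_range(clustered)
        assert sw is not None
        assert sw.cost_min < sw.cost_max
        # local efficiency beats the degree-preserving null at mid costs
        mid = clustered.table.iloc[len(grid) // 2]
        assert mid["e_loc"] > mid["e_loc_rand"]

        noise = efficiency_curves(
            noise_corr(rng), cost_grid=grid, n_null=8, seed=2
        )
        tbl = noise.table
        # observed efficiency of thresholded noise tracks the null closely
        assert np.allclose(tbl["e_glob"], tbl["e_glob_rand"], atol=0.05)

    def test_criterion_true_everywhere_spans_grid(self):
        import pandas as pd

        from costnet.metrics import EfficiencyCurve

        grid = [0.1, 0.2, 0.3]
        table = pd.DataFrame(
            {
                "cost": grid,
                "e_glob": [0.5, 0.6, 0.7],
                "e_loc": [0.6, 0.6, 0.6],
                "ce": [0.4, 0.4, 0.4],
                "e_glob_rand": [0.6, 0.7, 0.8],
                "e_loc_rand": [0.3, 0.3, 0.3],
                "e_glob_latt": [0.2, 0.3, 0.4],
            }
        )
        sw = small_world_cost_range(EfficiencyCurve(table, n_null=1, seed=0))
        assert (sw.cost_min, sw.cost_max) == (0.1, 0.3)

    def test_criterion_never_met_yields_empty_range(self):
        import pandas as pd

        from costnet.metrics import EfficiencyCurve

        table = pd.DataFrame(
            {
                "cost": [0.1, 0.2],
                "e_glob": [0.9, 0.9],
                "e_loc": [0.1, 0.1],
                "ce": [0.8, 0.7],
                "e_glob_rand": [0.6, 0.7],
                "e_loc_rand": [0.3, 0.3],
                "e_glob_latt": [0.2, 0.3],
            }
        )
        assert small_world_cost_range(EfficiencyCurve(table, n_null=1, seed=0)) is None


class TestSmoothAndPeak:
    def test_parabola_peak_recovered(self):
        grid = np.arange(0.1, 0.501, 0.05)
        ce = -((grid - 0.3) ** 2)
        assert smooth_and_peak(grid, ce) == pytest.approx(0.300, abs=0.001)

    def test_increasing_curve_peaks_at_max(self):
        grid = np.arange(0.1, 0.501, 0.1)
        assert smooth_and_peak(grid, grid * 2) == pytest.approx(0.5)

    def test_constant_curve_ties_resolve_to_min(self):
        grid = np.arange(0.1, 0.501, 0.1)
        assert smooth_and_peak(grid, np.ones_like(grid)) == pytest.approx(0.1)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            smooth_and_peak([0.1, 0.2, 0.3], [1, 2, 3])
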