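"""Placement, the five coupling generators, quantifiers and graph I/O."""

import itertools

import numpy as np
import pytest

import gliawave as gw
from gliawave.topology import (
    AstrocytePositions,
    CouplingNetwork,
    build_erdos_renyi,
    build_link_radius,
    build_regular_degree,
    build_shortcut,
    build_spatial_scale_free,
    calibrate_placement,
    lattice_indices,
    mean_degree,
    mean_shortest_path,
    nn_distance_stats,
    place_astrocytes,
    voronoi_adjacency,
)


class TestPlacement:
    def test_cell_count_and_unjittered_spacing(self):
        pos = place_astrocytes(4, 70.0, 0.0, seed=0)
        assert pos.n == 64
        mean, mn, cv = nn_distance_stats(pos)
        assert mean == pytest.approx(70.0)
        assert mn == pytest.approx(70.0)
        assert cv == pytest.approx(0.0, abs=1e-12)

    def test_invalid_arguments(self):
        with pytest.raises(ValueError):
            place_astrocytes(1, 70, 55)
        with pytest.raises(ValueError):
            place_astrocytes(5, -1, 55)
        with pytest.raises(ValueError):
            place_astrocytes(5, 70, 55, distribution="cauchy")

    def test_calibration_self_match(self):
        # targets taken from an unjittered lattice are matched by (a0, 0)
        a0 = 60.0
        pos = place_astrocytes(5, a0, 0.0, seed=0)
        mean, mn, cv = nn_distance_stats(pos)
        a_star, s_star = calibrate_placement(mean, mn, max(cv, 1e-6),
                                             a_grid=[50.0, a0, 70.0],
                                             sigma_grid=[0.0, 20.0],
                                             n_side=5, n_seeds=3)
        assert a_star == a0
        assert s_star == 0.0


class TestRegularDegree:
    def test_two_cells_single_edge(self):
        coords = np.array([[0.0, 0, 0], [50.0, 0, 0]])
        pos = AstrocytePositions(coords=coords, a=50, sigma=0)
        net = build_regular_degree(pos, k=1, seed=0)
        assert net.n_edges == 1

    def test_degree_cap_and_realized_mean(self):
        pos = place_astrocytes(11, 70, 55, seed=3)
        net = build_regular_degree(pos, k=3, seed=3)
        assert net.degrees().max() <= 3
        assert 2.8 <= mean_degree(net) <= 3.0


class TestLinkRadius:
    def test_degenerate_radii(self):
        pos = place_astrocytes(3, 70, 0.0, seed=0)
        assert build_link_radius(pos, 50.0).n_edges == 0  # below lattice spacing
        n = pos.n
        assert build_link_radius(pos, 1e4).n_edges == n * (n - 1) // 2

    def test_mean_degree_monotone_in_radius(self):
        pos = place_astrocytes(7, 70, 55, seed=1)
        degs = [mean_degree(build_link_radius(pos, d)) for d in (80, 90, 100, 110, 120)]
        assert all(a <= b for a, b in zip(degs, degs[1:]))


class TestShortcut:
    def test_unrewired_interior_degree(self):
        pos = place_astrocytes(5, 70, 0.0, seed=0)
        net = build_shortcut(pos, m_latt=1, p_s=0.0, seed=0)
        interior = pos.interior_mask()
        assert np.all(net.degrees()[interior] == 6)

    def test_rewiring_preserves_edge_count(self):
        pos = place_astrocytes(5, 70, 55, seed=2)
        n0 = build_shortcut(pos, 1, 0.0, seed=2).n_edges
        for p_s in (0.05, 0.5, 1.0):
            assert build_shortcut(pos, 1, p_s, seed=2).n_edges == n0

    def test_full_rewiring_shortens_paths(self):
        shorter = 0
        for s in range(5):
            pos = place_astrocytes(5, 70, 55, seed=s)
            L0, _ = mean_shortest_path(build_shortcut(pos, 1, 0.0, seed=s))
            L1, _ = mean_shortest_path(build_shortcut(pos, 1, 1.0, seed=s))
            shorter += L1 < L0
        assert shorter >= 4

    def test_multi_step_lattice_couplings(self):
        pos = place_astrocytes(5, 70, 0.0, seed=0)
        net = build_shortcut(pos, m_latt=2, p_s=0.0, seed=0)
        interior = lattice_indices(5)
        core = np.all((interior >= 2) & (interior <= 2), axis=1)  # exact centre
        assert net.degrees()[core][0] == 12  # 2 per axis per step, 2 steps


class TestSpatialScaleFree:
    def test_edge_count_formula(self):
        pos = place_astrocytes(5, 70, 55, seed=0)
        for m_sf in (2, 3):
            net = build_spatial_scale_free(pos, m_sf, 25.0, seed=0)
            expected = m_sf * (m_sf - 1) // 2 + m_sf * (pos.n - m_sf)
            assert net.n_edges == expected

    def test_large_rc_grows_hubs_and_edge_length(self):
        pos = place_astrocytes(11, 70, 55, seed=0)
        short = build_spatial_scale_free(pos, 3, 2.0, seed=0)
        long_ = build_spatial_scale_free(pos, 3, 105.0, seed=0)
        assert long_.degrees().max() > 20  # hubs
        assert short.degrees().max() < long_.degrees().max()

        def mean_len(net):
            return np.linalg.norm(
                pos.coords[net.edge_i] - pos.coords[net.edge_j], axis=1).mean()

        assert mean_len(short) < mean_len(long_)


class TestErdosRenyi:
    def test_degenerate_probabilities(self):
        assert build_erdos_renyi(20, 0.0, seed=0).n_edges == 0
        assert build_erdos_renyi(20, 1.0, seed=0).n_edges == 190

    def test_mean_degree_matches_binomial(self):
        n, p, reps = 200, 6 / 199, 20
        ks = [mean_degree(build_erdos_renyi(n, p, seed=s)) for s in range(reps)]
        expect = p * (n - 1)
        se = np.sqrt(2 * p * (1 - p) * (n - 1) / n / reps)  # SE of the mean of <k>
        assert abs(np.mean(ks) - expect) < 3 * se + 0.05


class TestVoronoi:
    def test_cube_centre_touches_all_corners(self):
        corners = np.array(list(itertools.product([0.0, 100.0], repeat=3)))
        coords = np.vstack([corners, [[50.0, 50.0, 50.0]]])
        pos = AstrocytePositions(coords=coords, a=100, sigma=0)
        net = voronoi_adjacency(pos)
        assert net.degrees()[8] == 8

    def test_degenerate_configuration_signalled(self):
        coords = np.zeros((6, 3))
        coords[:, 0] = np.arange(6)  # collinear
        pos = AstrocytePositions(coords=coords, a=1, sigma=0)
        with pytest.raises(ValueError):
            voronoi_adjacency(pos)


class TestQuantifiers:
    def test_mean_degree_closed_forms(self):
        complete = build_erdos_renyi(7, 1.0, seed=0)
        assert mean_degree(complete) == 6
        empty = build_erdos_renyi(7, 0.0, seed=0)
        assert mean_degree(empty) == 0

    def test_path_graph_mean_shortest_path(self):
        net = CouplingNetwork(3, np.array([0, 1]), np.array([1, 2]))
        L, frac = mean_shortest_path(net)
        assert L == pytest.approx(4 / 3)
        assert frac == 0.0

    def test_complete_graph_unit_distance(self):
        L, frac = mean_shortest_path(build_erdos_renyi(6, 1.0, seed=0))
        assert L == 1.0 and frac == 0.0

    def test_disconnected_fraction(self):
        # two cliques of 3: 9 of 15 unordered pairs disconnected
        ei = np.array([0, 0, 1, 3, 3, 4])
        ej = np.array([1, 2, 2, 4, 5, 5])
        L, frac = mean_shortest_path(CouplingNetwork(6, ei, ej))
        assert L == 1.0
        assert frac == pytest.approx(9 / 15)

    def test_against_brute_force_floyd_warshall(self, rng):
        for trial in range(5):
            n = int(rng.integers(10, 50))
            p = rng.uniform(0.05, 0.3)
            net = build_erdos_renyi(n, p, seed=int(rng.integers(2**31)))
            dist = np.full((n, n), np.inf)
            np.fill_diagonal(dist, 0)
            for i, j in zip(net.edge_i, net.edge_j):
                dist[i, j] = dist[j, i] = 1
            for k in range(n):
                dist = np.minimum(dist, dist[:, [k]] + dist[[k], :])
            off = ~np.eye(n, dtype=bool)
            finite = np.isfinite(dist) & off
            L, frac = mean_shortest_path(net)
            if finite.any():
                assert L == pytest.approx(dist[finite].mean())
            assert frac == pytest.approx(1 - finite.sum() / off.sum())

    def test_lattice_path_equals_mean_manhattan_distance(self):
        pos = place_astrocytes(5, 70, 0.0, seed=0)
        net = build_shortcut(pos, 1, 0.0, seed=0)
        idx = lattice_indices(5)
        diff = np.abs(idx[:, None, :] - idx[None, :, :]).sum(axis=2)
        off = ~np.eye(len(idx), dtype=bool)
        L, frac = mean_shortest_path(net)
        assert frac == 0.0
        assert L == pytest.approx(diff[off].mean())


class TestNetworkContainer:
    def test_simple_graph_enforced(self):
        with pytest.raises(ValueError):
            CouplingNetwork(3, np.array([0]), np.array([0]))  # self loop
        with pytest.raises(ValueError):
            CouplingNetwork(3, np.array([0, 1]), np.array([1, 0]))  # duplicate

    def test_strength_sign_and_symmetry(self):
        net = CouplingNetwork(3, np.array([0, 1]), np.array([1, 2]),
                              strengths=np.array([0.5, 1.5]))
        adj = net.adjacency().toarray()
        np.testing.assert_array_equal(adj, adj.T)
        with pytest.raises(ValueError):
            CouplingNetwork(3, np.array([0]), np.array([1]), strengths=np.array([-1.0]))

    def test_subgraph_relabels_and_filters(self):
        net = CouplingNetwork(4, np.array([0, 1, 2]), np.array([1, 2, 3]))
        sub = net.subgraph(np.array([True, True, False, True]))
        assert sub.n_nodes == 3
        assert sub.n_edges == 1  # only (0,1) survives


class TestIO:
    def test_positions_roundtrip(self, tmp_path):
        pos = place_astrocytes(3, 70, 55, seed=0)
        path = tmp_path / "pos.csv"
        gw.topology.save_positions(pos, path)
        back = gw.topology.load_positions(path)
        np.testing.assert_allclose(back.coords, pos.coords)

    def test_edge_list_roundtrip_with_strengths(self, tmp_path):
        net = CouplingNetwork(4, np.array([0, 1]), np.array([2, 3]),
                              strengths=np.array([0.25, 1.75]))
        path = tmp_path / "net.tsv"
        gw.topology.save_edge_list(net, path)
        back = gw.topology.load_edge_list(path, n_nodes=4)
        np.testing.assert_array_equal(back.edge_i, net.edge_i)
        np.testing.assert_array_equal(back.edge_j, net.edge_j)
        np.testing.assert_allclose(back.strengths, net.strengths)

    def test_graphml_roundtrip(self, tmp_path):
        pos = place_astrocytes(3, 70, 55, seed=1)
        net = build_link_radius(pos, 90.0)
        path = tmp_path / "net.graphml"
        gw.topology.save_graphml(net, path)
        back = gw.topology.load_graphml(path)
        assert back.n_nodes == net.n_nodes
        np.testing.assert_array_equal(back.edge_i, net.edge_i)
        np.testing.assert_array_equal(back.edge_j, net.edge_j)
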