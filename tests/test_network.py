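"""Correlation networks, communities, betweenness and paths."""

import math

import networkx as nx
import numpy as np
import pytest

from actintools import model_io, synthetic
from actintools.network import (
    DynamicNetwork,
    NetworkParams,
    brute_force_edge_betweenness,
    brute_force_shortest_path,
    build_network,
    contact_map,
    critical_elements,
    dccm,
    edge_betweenness,
    girvan_newman,
    network_difference,
    suboptimal_paths,
)
from tests.conftest import build_system, make_trajectory


def network_from_graph(g: nx.Graph) -> DynamicNetwork:
    """Wrap a prebuilt weighted graph for the analysis functions."""
    nodes = sorted(g.nodes)
    n = len(nodes)
    return DynamicNetwork(
        nodes=nodes,
        correlation=np.eye(n),
        contacts=np.zeros((n, n), dtype=bool),
        graph=g,
    )


class TestDCCM:
    def _system(self, n):
        return build_system(
            [(i + 1, "ALA", [("CA", "C", [4.0 * i, 0.0, 0.0])]) for i in range(n)]
        )

    def test_identical_motion_gives_unit_correlation(self):
        system = self._system(5)
        base = system.coordinates()
        rng = np.random.default_rng(0)
        frames = np.stack([base + rng.normal(0, 1, 3) for _ in range(50)])
        # residues 1 and 2 share an extra identical displacement
        extra = rng.normal(0, 1, (50, 3))
        frames[:, 0, :] += extra
        frames[:, 1, :] += extra
        c = dccm(frames, np.arange(5))
        assert c[0, 1] == pytest.approx(1.0, abs=0.05)

    def test_antiphase_motion_gives_negative_unit(self):
        system = self._system(5)
        base = system.coordinates()
        rng = np.random.default_rng(1)
        frames = np.stack([base.copy() for _ in range(50)])
        extra = rng.normal(0, 1, (50, 3))
        frames[:, 0, :] += extra
        frames[:, 1, :] -= extra
        # uncorrelated motion elsewhere stabilizes the superposition
        frames[:, 2:, :] += rng.normal(0, 0.3, (50, 3, 3))
        c = dccm(frames, np.arange(5))
        assert c[0, 1] == pytest.approx(-1.0, abs=0.1)

    def test_symmetric_unit_diagonal_bounded(self, scaffold, scaffold_view):
        motion = synthetic.MotionModel(noise=synthetic.NoiseSpec(sigma_A=0.5))
        traj, _ = synthetic.generate_trajectory(scaffold, motion, 60, seed=2)
        c = dccm(traj, scaffold_view.ca_array())
        np.testing.assert_allclose(c, c.T, atol=1e-12)
        np.testing.assert_allclose(np.diag(c), 1.0)
        assert np.nanmax(np.abs(c)) <= 1.0 + 1e-12

    def test_planted_blocks_recovered(self):
        csys, blocks = synthetic.make_community_scaffold(seed=0)
        motion = synthetic.MotionModel(
            noise=synthetic.NoiseSpec(sigma_A=0.5, blocks=blocks, rho_in=0.8)
        )
        traj, _ = synthetic.generate_trajectory(csys, motion, 2000, seed=3)
        view = model_io.ProtomerView(csys, "A")
        c = dccm(traj, view.ca_array())
        n = len(blocks[0])
        in_block = c[:n, :n][np.triu_indices(n, 1)].mean()
        assert in_block > 0.4  # reduced from 0.8 by the global fit


class TestContactMap:
    def _frames(self, positions, n_frames=4):
        system = build_system(
            [(i + 1, "ALA", [("CA", "C", p)]) for i, p in enumerate(positions)]
        )
        base = system.coordinates()
        return system, np.stack([base] * n_frames)

    def test_persistent_contact_within_cutoff(self):
        system, frames = self._frames([[0, 0, 0], [0, 10, 0], [4.0, 0, 0]])
        view = model_io.ProtomerView(system, "A")
        contacts = contact_map(frames, view)
        assert contacts[0, 2] and contacts[2, 0]

    def test_half_occupancy_fails_default_threshold(self):
        system, frames = self._frames([[0, 0, 0], [0, 10, 0], [4.0, 0, 0]], 4)
        frames[2:, 2, 0] = 20.0  # contact present in only 50% of frames
        view = model_io.ProtomerView(system, "A")
        contacts = contact_map(frames, view)
        assert not contacts[0, 2]

    def test_sequence_neighbors_excluded(self):
        system, frames = self._frames([[0, 0, 0], [3.0, 0, 0], [30, 0, 0]])
        view = model_io.ProtomerView(system, "A")
        contacts = contact_map(frames, view)
        assert not contacts[0, 1]


class TestBuildNetwork:
    def test_edge_weights_are_neg_log_correlation(self):
        corr = np.array([[1.0, 0.5], [0.5, 1.0]])
        contacts = np.array([[False, True], [True, False]])
        net = build_network(corr, contacts, [("A", 1), ("A", 3)])
        w = net.graph[("A", 1)][("A", 3)]["weight"]
        assert w == pytest.approx(math.log(2), abs=1e-12)

    def test_unit_correlation_gives_zero_weight(self):
        corr = np.array([[1.0, 1.0], [1.0, 1.0]])
        contacts = np.array([[False, True], [True, False]])
        net = build_network(corr, contacts, [("A", 1), ("A", 3)])
        assert net.graph[("A", 1)][("A", 3)]["weight"] == 0.0

    def test_no_contacts_no_edges(self):
        corr = np.eye(3)
        net = build_network(
            corr, np.zeros((3, 3), dtype=bool), [("A", i) for i in (1, 3, 5)]
        )
        assert net.graph.number_of_edges() == 0


class TestCommunities:
    def _two_cliques_with_bridge(self):
        g = nx.Graph()
        for base in (0, 10):
            for i in range(5):
                for j in range(i + 1, 5):
                    g.add_edge(("A", base + i), ("A", base + j), weight=0.2)
        g.add_edge(("A", 4), ("A", 10), weight=0.2)
        return network_from_graph(g)

    def test_two_cliques_split_at_bridge(self):
        part = girvan_newman(self._two_cliques_with_bridge())
        assert len(part.communities) == 2
        sizes = sorted(len(c) for c in part.communities)
        assert sizes == [5, 5]

    def test_complete_graph_stays_one_community(self):
        g = nx.complete_graph(6)
        g = nx.relabel_nodes(g, {i: ("A", i) for i in range(6)})
        nx.set_edge_attributes(g, 1.0, "weight")
        part = girvan_newman(network_from_graph(g))
        assert len(part.communities) == 1

    def test_planted_blocks_recovered_across_seeds(self):
        from sklearn.metrics import adjusted_rand_score

        for seed in range(3):
            csys, blocks = synthetic.make_community_scaffold(seed=seed)
            motion = synthetic.MotionModel(
                noise=synthetic.NoiseSpec(sigma_A=0.5, blocks=blocks, rho_in=0.8)
            )
            traj, _ = synthetic.generate_trajectory(
                csys, motion, 1200, seed=50 + seed
            )
            view = model_io.ProtomerView(csys, "A")
            c = dccm(traj, view.ca_array())
            contacts = contact_map(traj, view)
            keys = [("A", r) for r in view.residue_numbers]
            net = build_network(c, contacts, keys)
            part = girvan_newman(net)
            truth = [b for b, blk in enumerate(blocks) for _ in blk]
            pred = [part.membership[("A", r)] for blk in blocks for r in blk]
            assert adjusted_rand_score(truth, pred) == 1.0

    def test_critical_elements_are_inter_community_bridges(self):
        net = self._two_cliques_with_bridge()
        part = girvan_newman(net)
        part = critical_elements(net, part)
        assert part.critical_edges[0] == (("A", 4), ("A", 10))
        assert set(part.critical_nodes[:2]) == {("A", 4), ("A", 10)}


class TestBetweenness:
    def test_path_graph_matches_documented_convention(self):
        g = nx.Graph()
        g.add_edge("a", "b", weight=1.0)
        g.add_edge("b", "c", weight=1.0)
        net = network_from_graph(g)
        bw = edge_betweenness(net)
        # ordered pairs through ab: (a,b),(b,a),(a,c),(c,a) -> 4
        assert bw[("a", "b")] == pytest.approx(4.0)
        assert bw[("b", "c")] == pytest.approx(4.0)
        ref = brute_force_edge_betweenness(g)
        for e, v in bw.items():
            assert v == pytest.approx(ref[e])

    def test_star_graph_edges_equal_by_symmetry(self):
        g = nx.star_graph(4)
        nx.set_edge_attributes(g, 1.0, "weight")
        bw = edge_betweenness(network_from_graph(g))
        assert len(set(round(v, 9) for v in bw.values())) == 1

    def test_bridge_between_cliques_has_maximum_betweenness(self):
        g = nx.Graph()
        for base in (0, 10):
            for i in range(4):
                for j in range(i + 1, 4):
                    g.add_edge(base + i, base + j, weight=1.0)
        g.add_edge(3, 10, weight=1.0)
        bw = edge_betweenness(network_from_graph(g))
        assert max(bw, key=bw.get) == (3, 10)

    def test_matches_brute_force_on_random_graphs(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            n = int(rng.integers(3, 8))
            g = nx.gnp_random_graph(n, 0.5, seed=int(rng.integers(10**6)))
            for u, v in g.edges:
                g[u][v]["weight"] = float(rng.uniform(0.1, 2.0))
            bw = edge_betweenness(network_from_graph(g))
            ref = brute_force_edge_betweenness(g)
            for e in bw:
                assert bw[e] == pytest.approx(ref[e], abs=1e-9)


class TestSuboptimalPaths:
    def test_direct_edge_has_no_intermediates(self):
        g = nx.Graph()
        g.add_edge("s", "t", weight=1.0)
        out = suboptimal_paths(network_from_graph(g), "s", "t")
        assert len(out) == 1
        assert out[0].intermediate_count == 0

    def test_zero_tolerance_returns_unique_shortest(self):
        g = nx.Graph()
        g.add_edge("s", "m", weight=1.0)
        g.add_edge("m", "t", weight=1.0)
        g.add_edge("s", "t", weight=5.0)
        out = suboptimal_paths(network_from_graph(g), "s", "t",
                               tolerance_fraction=0.0)
        assert len(out) == 1
        assert out[0].nodes == ["s", "m", "t"]

    def test_tolerance_admits_near_optimal_paths(self):
        g = nx.Graph()
        g.add_edge("s", "m", weight=1.0)
        g.add_edge("m", "t", weight=1.0)
        g.add_edge("s", "t", weight=2.1)
        out = suboptimal_paths(network_from_graph(g), "s", "t",
                               tolerance_fraction=0.1)
        assert [p.nodes for p in out] == [["s", "m", "t"], ["s", "t"]]

    def test_disconnected_pair_reports_no_pathway(self):
        g = nx.Graph()
        g.add_nodes_from(["s", "t"])
        g.add_edge("s", "x", weight=1.0)
        out = suboptimal_paths(network_from_graph(g), "s", "t")
        assert len(out) == 1
        assert not out[0].exists
        assert out[0].total_weight == math.inf

    def test_matches_exhaustive_enumeration_on_random_graphs(self):
        rng = np.random.default_rng(6)
        checked = 0
        while checked < 20:
            n = int(rng.integers(4, 8))
            g = nx.gnp_random_graph(n, 0.5, seed=int(rng.integers(10**6)))
            for u, v in g.edges:
                g[u][v]["weight"] = float(rng.uniform(0.1, 2.0))
            s, t = 0, n - 1
            if s not in g or t not in g:
                continue
            out = suboptimal_paths(network_from_graph(g), s, t)[0]
            ref = brute_force_shortest_path(g, s, t)
            if ref is None:
                assert not out.exists
            else:
                assert out.total_weight == pytest.approx(ref[1], abs=1e-9)
            checked += 1


class TestNetworkDifference:
    def _net(self, edges):
        g = nx.Graph()
        g.add_nodes_from([("A", i) for i in range(1, 5)])
        for u, v, w in edges:
            g.add_edge(("A", u), ("A", v), weight=w)
        return network_from_graph(g)

    def test_identical_networks_have_empty_unique_sets(self):
        a = self._net([(1, 3, 0.5), (2, 4, 0.7)])
        b = self._net([(1, 3, 0.5), (2, 4, 0.7)])
        d = network_difference(a, b)
        assert d["unique_to_a"] == {} and d["unique_to_b"] == {}
        assert len(d["shared"]) == 2

    def test_disjoint_edge_sets_fully_unique(self):
        a = self._net([(1, 3, 0.5)])
        b = self._net([(2, 4, 0.7)])
        d = network_difference(a, b)
        assert list(d["unique_to_a"]) == [(("A", 1), ("A", 3))]
        assert list(d["unique_to_b"]) == [(("A", 2), ("A", 4))]
        assert d["shared"] == {}

    def test_removed_edge_appears_in_other_unique_set(self):
        a = self._net([(1, 3, 0.5)])
        b = self._net([(1, 3, 0.5), (2, 4, 0.7)])
        d = network_difference(a, b)
        assert list(d["unique_to_b"]) == [(("A", 2), ("A", 4))]

    def test_node_universe_mismatch_rejected(self):
        a = self._net([(1, 3, 0.5)])
        g = nx.Graph()
        g.add_nodes_from([("B", i) for i in range(1, 5)])
        with pytest.raises(ValueError):
            network_difference(a, network_from_graph(g))


class TestRerouting:
    def test_tethered_node_loses_shortest_path_traffic(self):
        tsys, info = synthetic.make_crosslink_testbed(seed=0)
        view = model_io.ProtomerView(tsys, "A")

        def net_for(constraint=None):
            motion = synthetic.MotionModel(
                noise=synthetic.NoiseSpec(
                    sigma_A=0.25, blocks=info["blocks"], rho_in=0.7
                )
            )
            if constraint is not None:
                motion = synthetic.apply_crosslink_constraint(motion, constraint)
            traj, _ = synthetic.generate_trajectory(tsys, motion, 600, seed=17)
            c = dccm(traj, view.ca_array())
            contacts = contact_map(traj, view)
            keys = [("A", r) for r in view.residue_numbers]
            return build_network(c, contacts, keys)

        control = net_for()
        p_control = suboptimal_paths(control, info["source"], info["target"])[0]
        assert info["tethered"] in p_control.nodes

        tether = synthetic.CrosslinkConstraint(
            anchor_point=info["anchor_point"], stiffness=0.9
        )
        tethered = net_for(tether)
        p_tethered = suboptimal_paths(tethered, info["source"], info["target"])[0]
        assert p_tethered.exists
        assert info["tethered"] not in p_tethered.nodes
        assert p_tethered.intermediate_count > p_control.intermediate_count

    def test_planted_contact_geometry_clears_margins(self):
        """Every intended contact sits well inside the cutoff and every
        intended non-contact well outside (brute-force distances)."""
        tsys, _ = synthetic.make_crosslink_testbed(seed=0)
        coords = tsys.coordinates()
        view = model_io.ProtomerView(tsys, "A")
        nums = view.residue_numbers
        params = NetworkParams()
        for i, a in enumerate(nums):
            for b in nums[i + 1:]:
                d = np.linalg.norm(
                    coords[view.ca_indices[a]] - coords[view.ca_indices[b]]
                )
                assert not (4.2 < d < 4.8), (a, b, d)
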