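import math

import networkx as nx
import numpy as np
import pytest

from fibronet import (
    CouplingConfig,
    DDMConfig,
    build_fibre_network,
    find_substrate,
    shortest_return_length,
    simulate_block,
)
from fibronet.network import TRANSVERSE
from fibronet.testing import net_from_graph, nx_return_length, random_small_graph


class TestSimulateBlock:
    def test_long_ring_reenters(self):
        net = net_from_graph(nx.cycle_graph(40))
        cfg = DDMConfig(tau=30)
        reentry, loop = simulate_block(net, 0, 1, cfg)
        assert reentry
        assert len(loop) == 40  # the full ring
        assert shortest_return_length(net, 0, 1) == 40  # >= tau, brute force

    def test_short_ring_does_not_reenter(self):
        net = net_from_graph(nx.cycle_graph(20))
        reentry, loop = simulate_block(net, 0, 1, DDMConfig(tau=30))
        assert not reentry and loop is None

    def test_trees_never_reenter(self):
        for seed in range(5):
            g = nx.random_labeled_tree(25, seed=seed)
            net = net_from_graph(nx.convert_node_labels_to_integers(g))
            for u, v in g.edges():
                assert not simulate_block(net, u, v, DDMConfig(tau=3))[0]
                assert not simulate_block(net, v, u, DDMConfig(tau=3))[0]

    def test_nonadjacent_nodes_rejected(self):
        net = net_from_graph(nx.cycle_graph(10))
        with pytest.raises(ValueError, match="not adjacent"):
            simulate_block(net, 0, 5, DDMConfig(tau=3))

    def test_disconnected_pacing_is_trivially_false(self, caplog):
        net = net_from_graph(nx.cycle_graph(40))
        cfg = DDMConfig(tau=4, pacing=[20])
        # block on the far side is still reached; pacing an absent wave is
        # exercised by pacing a node whose wave is annihilated at the block
        g = nx.disjoint_union(nx.cycle_graph(40), nx.path_graph(3))
        net2 = net_from_graph(g)
        reentry, _ = simulate_block(net2, 0, 1, DDMConfig(tau=4, pacing=[41]))
        assert not reentry
        assert any("trivially false" in r.message for r in caplog.records)


class TestShortestReturn:
    def test_cycle_return_is_cycle_length(self):
        for n in (5, 12, 30):
            net = net_from_graph(nx.cycle_graph(n))
            assert shortest_return_length(net, 0, 1) == n

    def test_tree_return_is_infinite(self):
        g = nx.convert_node_labels_to_integers(nx.random_labeled_tree(15, seed=2))
        net = net_from_graph(g)
        u, v = next(iter(g.edges()))
        assert shortest_return_length(net, u, v) == math.inf

    def test_ladder_matches_exhaustive_path_search(self):
        # two parallel chains of length L bridged at both ends
        for L in (4, 7, 10):
            g = nx.Graph()
            for i in range(L):
                g.add_edge(i, i + 1)  # chain A: 0..L
                g.add_edge(L + 1 + i, L + 2 + i)  # chain B
            g.add_edge(0, L + 1)
            g.add_edge(L, 2 * L + 1)
            net = net_from_graph(g)
            got = shortest_return_length(net, 1, 0)
            # brute force over all simple alternative paths
            h = g.copy()
            h.remove_edge(0, 1)
            best = min(len(p) - 1 for p in nx.all_simple_paths(h, 0, 1)) + 1
            assert got == best == 2 * L + 2

    def test_symmetry_in_direction(self):
        g = random_small_graph(17)
        net = net_from_graph(g)
        for u, v in g.edges():
            assert shortest_return_length(net, u, v) == shortest_return_length(
                net, v, u
            )


class TestOracleEquivalence:
    @pytest.mark.parametrize("tau", [3, 5, 10])
    def test_simulation_matches_graph_criterion(self, tau):
        # the module's core property: the DDM and the shortest-return
        # criterion identify the same substrate, with networkx as the
        # independent route for the return lengths
        cfg = DDMConfig(tau=tau)
        for seed in range(30):
            g = random_small_graph(seed)
            net = net_from_graph(g)
            for u, v in g.edges():
                for node, blocked in ((u, v), (v, u)):
                    expected = nx_return_length(g, node, blocked)
                    sim, loop = simulate_block(net, node, blocked, cfg)
                    assert sim == (expected >= tau and expected < math.inf), (
                        seed,
                        node,
                        blocked,
                    )
                    if sim:
                        assert len(loop) == expected


class TestFindSubstrate:
    def test_matches_per_edge_oracle(self):
        cfg = DDMConfig(tau=5)
        for seed in (3, 8, 21):
            g = random_small_graph(seed)
            net = net_from_graph(g)
            result = find_substrate(net, cfg)
            got = {tuple(p) for p in result.pairs}
            expected = set()
            for u, v in g.edges():
                L = nx_return_length(g, u, v)
                if 5 <= L < math.inf:
                    expected.add((u, v))
                    expected.add((v, u))
            assert got == expected
            assert result.n_opportunities == 2 * g.number_of_edges()

    def test_monotone_in_tau(self):
        g = random_small_graph(5)
        net = net_from_graph(g)
        subs = {
            tau: {tuple(p) for p in find_substrate(net, DDMConfig(tau=tau)).pairs}
            for tau in (3, 5, 10)
        }
        assert subs[10] <= subs[5] <= subs[3]

    def test_acyclic_network_has_empty_substrate(self):
        g = nx.convert_node_labels_to_integers(nx.random_labeled_tree(30, seed=1))
        net = net_from_graph(g)
        for tau in (2, 3, 8):
            assert find_substrate(net, DDMConfig(tau=tau)).n_substrates == 0

    def test_tight_fibre_coupling_gives_disjoint_chains_and_no_substrate(
        self, slab_tracts
    ):
        # c -> 0 with steep fall-off: no transverse edges survive, the
        # network is a union of chains, and chains carry no loops
        net = build_fibre_network(slab_tracts, CouplingConfig(c=0.0, r=50.0, seed=0))
        assert (net.kinds == TRANSVERSE).sum() == 0
        assert find_substrate(net, DDMConfig(tau=5)).n_substrates == 0

    def test_ring_of_rings(self):
        # one large ring above threshold, small rings below it
        g = nx.cycle_graph(40)
        small = nx.cycle_graph(5)
        g = nx.disjoint_union(g, small)
        g.add_edge(0, 40)  # bridge
        net = net_from_graph(g)
        result = find_substrate(net, DDMConfig(tau=30))
        assert set(result.substrate_nodes) == set(range(40))
        for c in result.circuits:
            assert c.length >= 30

    def test_adding_an_edge_can_destroy_the_substrate(self):
        # denser coupling shortens return paths below tau: the compact-
        # fibrosis limit where loops are too short for reentry
        ring = nx.cycle_graph(40)
        net = net_from_graph(ring)
        assert find_substrate(net, DDMConfig(tau=30)).n_substrates > 0
        ring.add_edge(0, 20)  # chord
        net2 = net_from_graph(ring)
        result = find_substrate(net2, DDMConfig(tau=30))
        assert result.n_substrates == 0
        # brute-force confirmation on the chord graph
        for u, v in ring.edges():
            assert nx_return_length(ring, u, v) < 30

    def test_circuit_voxel_counts_consistent(self):
        g = nx.cycle_graph(35)
        net = net_from_graph(g)
        result = find_substrate(net, DDMConfig(tau=30))
        # every directed block on the ring induces; each circuit covers all
        # 35 voxels, so each voxel count equals the number of circuits
        assert result.n_substrates == 70
        assert len(result.circuits) == 35  # one per undirected edge
        expected = np.zeros_like(result.per_voxel_counts)
        for c in result.circuits:
            vox = c.voxel_set(net.voxels)
            expected[vox[:, 0], vox[:, 1], vox[:, 2]] += 1
        assert np.array_equal(result.per_voxel_counts, expected)

    def test_horizon_bounds_detected_loops(self):
        net = net_from_graph(nx.cycle_graph(50))
        full = find_substrate(net, DDMConfig(tau=10))
        assert full.n_substrates == 100
        capped = find_substrate(net, DDMConfig(tau=10, max_steps=30))
        assert capped.n_substrates == 0  # the only loop is longer than 30
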