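"""Contact occupancy, edge weighting, communities, optimal/suboptimal paths."""

import itertools
import math

import networkx as nx
import numpy as np
import pytest

import allodyn
from allodyn.correlation import CorrelationMatrix
from allodyn.errors import AnalysisError
from allodyn.network import (
    ContactMap,
    contact_occupancy,
    detect_communities,
    floyd_warshall,
    intercommunity_connectivity,
    optimal_path,
    suboptimal_paths,
    weight_edges,
)
from allodyn.synthetic import build_toy_complex, community_study_spec
from allodyn.trajectory import AtomRecord, Ensemble, StructureModel


def chain_ensemble(n_res, frames):
    """n_res single-atom residues with given (F, n_res, 3) coordinates."""
    atoms = [
        AtomRecord(i + 1, "CA", "GLY", i + 1, "A", "C", tuple(frames[0][i]))
        for i in range(n_res)
    ]
    return Ensemble(np.asarray(frames, float), StructureModel(atoms))


def graph_from_weights(edges):
    g = nx.Graph()
    for u, v, w in edges:
        g.add_edge(("A", u), ("A", v), weight=w, absC=math.exp(-w), occupancy=1.0)
    return g


class TestContactOccupancy:
    def test_persistent_contact_has_full_occupancy(self):
        coords = np.array([[0, 0, 0], [3, 0, 0], [20, 0, 0]], float)
        ens = chain_ensemble(3, np.repeat(coords[None], 4, 0))
        cm = contact_occupancy(ens, "chain A", neighbor_exclusion=0)
        assert cm.occupancy[0, 1] == 1.0 and cm.adjacency[0, 1]
        assert not cm.adjacency[0, 2]

    def test_half_time_contact_fails_75_percent_gate(self):
        near = np.array([[0, 0, 0], [0, 20.0, 0], [4.0, 0, 0]], float)
        far = near.copy()
        far[2, 0] = 10.0  # residues 1 and 3 in contact only half the time
        frames = np.array([near, far, near, far])
        ens = chain_ensemble(3, frames)
        cm = contact_occupancy(ens, "chain A", neighbor_exclusion=1)
        assert cm.occupancy[0, 2] == pytest.approx(0.5)
        assert not cm.adjacency[0, 2]

    def test_matches_brute_force_frame_loop(self, path_fixture):
        fitted, *_ = path_fixture
        sub = Ensemble(fitted.frames[:50], fitted.topology)
        cm = contact_occupancy(sub, "chain A")
        idx = allodyn.resolve_selection(sub, "chain A")
        atoms = sub.topology.atoms
        groups = {}
        for i in idx:
            groups.setdefault((atoms[i].chain_id, atoms[i].residue_id), []).append(i)
        nodes = list(groups)
        for a, b in itertools.combinations(range(len(nodes)), 2):
            count = 0
            for f in range(sub.n_frames):
                dmin = min(
                    np.linalg.norm(sub.frames[f][i] - sub.frames[f][j])
                    for i in groups[nodes[a]]
                    for j in groups[nodes[b]]
                )
                count += dmin <= 4.5
            assert cm.occupancy[a, b] == pytest.approx(count / sub.n_frames, abs=1e-12)

    def test_sequence_neighbors_excluded(self):
        coords = np.array([[0, 0, 0], [3, 0, 0], [6, 0, 0]], float)
        ens = chain_ensemble(3, np.repeat(coords[None], 2, 0))
        cm = contact_occupancy(ens, "chain A", neighbor_exclusion=1)
        assert not cm.adjacency[0, 1] and not cm.adjacency[1, 2]

    def test_raising_occupancy_never_adds_edges(self, path_fixture):
        fitted, *_ = path_fixture
        sub = Ensemble(fitted.frames[:50], fitted.topology)
        lo = contact_occupancy(sub, "chain A", min_occupancy=0.5)
        hi = contact_occupancy(sub, "chain A", min_occupancy=0.9)
        assert not np.any(hi.adjacency & ~lo.adjacency)


class TestWeightEdges:
    def _contacts_and_corr(self, absC):
        nodes = [("A", 1), ("A", 3)]
        occ = np.array([[0.0, 1.0], [1.0, 0.0]])
        adj = occ >= 0.75
        cm = ContactMap(nodes, occ, adj, 4.5, 0.75, "heavy", 1)
        mat = np.array([[1.0, absC], [absC, 1.0]])
        return cm, CorrelationMatrix(mat, nodes)

    @pytest.mark.parametrize(
        "absC,expected",
        [(1.0, 0.0), (math.exp(-1.0), 1.0), (0.5, math.log(2.0))],
    )
    def test_log_identities(self, absC, expected):
        cm, corr = self._contacts_and_corr(absC)
        g = weight_edges(cm, corr)
        assert g[("A", 1)][("A", 3)]["weight"] == pytest.approx(expected, abs=1e-9)

    def test_zero_correlation_edge_dropped(self):
        cm, corr = self._contacts_and_corr(0.0)
        g = weight_edges(cm, corr)
        assert g.number_of_edges() == 0

    def test_masked_correlation_drops_edge_with_warning(self):
        cm, corr = self._contacts_and_corr(0.5)
        corr.matrix[0, 1] = corr.matrix[1, 0] = np.nan
        with pytest.warns(UserWarning, match="masked"):
            g = weight_edges(cm, corr)
        assert g.number_of_edges() == 0


class TestFloydWarshall:
    def random_graph(self, seed, n=10, p=0.4):
        rng = np.random.default_rng(seed)
        g = nx.Graph()
        for i in range(n):
            g.add_node(("A", i))
        for i in range(n):
            for j in range(i + 1, n):
                if rng.random() < p:
                    g.add_edge(("A", i), ("A", j), weight=float(rng.uniform(0.05, 2.0)))
        return g

    def test_equals_dijkstra_on_50_random_graphs(self):
        for seed in range(50):
            g = self.random_graph(seed)
            nodes, dist, _ = floyd_warshall(g)
            dj = dict(nx.all_pairs_dijkstra_path_length(g, weight="weight"))
            for i, u in enumerate(nodes):
                for j, v in enumerate(nodes):
                    expected = dj[u].get(v, math.inf)
                    assert dist[i, j] == pytest.approx(expected, abs=1e-9)

    def test_direct_edge_beats_cheaper_looking_two_hop(self):
        g = graph_from_weights([(1, 3, 0.5), (1, 2, 0.3), (2, 3, 0.3)])
        p = optimal_path(g, 1, 3)
        assert [n[1] for n in p.nodes] == [1, 3]
        assert p.length == pytest.approx(0.5)

    def test_source_equals_target(self):
        g = graph_from_weights([(1, 2, 0.5)])
        p = optimal_path(g, 1, 1)
        assert p.nodes == [("A", 1)] and p.length == 0.0 and p.n_residues == 1

    def test_disconnected_pair_gives_no_path_result(self):
        g = graph_from_weights([(1, 2, 0.5)])
        g.add_node(("A", 9))
        p = optimal_path(g, 1, 9)
        assert not p.reachable and p.nodes == []

    def test_matches_exhaustive_enumeration(self):
        for seed in range(10):
            g = self.random_graph(seed, n=6, p=0.6)
            nodes = sorted(g.nodes)
            s, t = nodes[0], nodes[-1]
            best = math.inf
            for path in nx.all_simple_paths(g, s, t):
                w = sum(g[a][b]["weight"] for a, b in zip(path, path[1:]))
                best = min(best, w)
            p = optimal_path(g, s, t)
            if math.isinf(best):
                assert not p.reachable
            else:
                assert p.length == pytest.approx(best, abs=1e-9)

    def test_path_length_decomposes_edge_by_edge(self):
        g = self.random_graph(4, n=8, p=0.3)
        nodes = sorted(g.nodes)
        pairs = [
            (s, t)
            for s in nodes
            for t in nodes
            if s < t and optimal_path(g, s, t).reachable and len(optimal_path(g, s, t).nodes) >= 3
        ]
        assert pairs, "random graph lacks a multi-hop shortest path"
        s, t = pairs[0]
        p = optimal_path(g, s, t)
        first_edge = g[p.nodes[0]][p.nodes[1]]["weight"]
        rest = optimal_path(g, p.nodes[1], t)
        assert rest.length == pytest.approx(p.length - first_edge, abs=1e-9)


class TestSuboptimalPaths:
    def test_equal_length_routes_both_returned_in_order(self):
        g = graph_from_weights([(1, 2, 0.4), (2, 4, 0.4), (1, 3, 0.4), (3, 4, 0.4)])
        paths = suboptimal_paths(g, 1, 4, delta=0.0)
        assert len(paths) == 2
        assert [n[1] for n in paths[0].nodes] == [1, 2, 4]
        assert [n[1] for n in paths[1].nodes] == [1, 3, 4]

    def test_zero_delta_returns_only_optimal_length(self):
        g = graph_from_weights([(1, 2, 0.3), (2, 4, 0.3), (1, 4, 0.7)])
        paths = suboptimal_paths(g, 1, 4, delta=0.0)
        assert len(paths) == 1 and paths[0].length == pytest.approx(0.6)

    def test_matches_exhaustive_simple_path_filter(self):
        rng = np.random.default_rng(9)
        g = nx.Graph()
        for i in range(7):
            for j in range(i + 1, 7):
                if rng.random() < 0.6:
                    g.add_edge(("A", i), ("A", j), weight=float(rng.uniform(0.1, 1.0)))
        s, t = ("A", 0), ("A", 6)
        opt = optimal_path(g, s, t).length
        delta = 1.5
        expected = []
        for path in nx.all_simple_paths(g, s, t):
            w = sum(g[a][b]["weight"] for a, b in zip(path, path[1:]))
            if w <= opt + delta + 1e-12:
                expected.append((w, path))
        expected.sort(key=lambda x: (x[0], x[1]))
        got = suboptimal_paths(g, s, t, delta=delta)
        assert len(got) == len(expected)
        for p, (w, path) in zip(got, expected):
            assert p.length == pytest.approx(w, abs=1e-9)
            assert p.nodes == path

    def test_scaled_integer_length_convention(self):
        g = graph_from_weights([(1, 2, 1.237)])
        p = optimal_path(g, 1, 2)
        assert p.length_x100 == 124


class TestCommunities:
    def two_cliques(self):
        g = nx.Graph()
        for base in (0, 10):
            for i, j in itertools.combinations(range(6), 2):
                g.add_edge(("A", base + i), ("A", base + j), weight=0.2, absC=0.8)
        g.add_edge(("A", 5), ("A", 10), weight=2.0, absC=0.1)
        return g

    def test_two_cliques_split_at_bridge(self):
        part = detect_communities(self.two_cliques())
        labels = part.labels
        groups = {}
        for node, lab in labels.items():
            groups.setdefault(lab, set()).add(node[1])
        assert len(groups) == 2
        assert {frozenset(v) for v in groups.values()} == {
            frozenset(range(6)),
            frozenset(range(10, 16)),
        }
        assert -0.5 <= part.modularity <= 1.0

    def test_single_clique_stays_whole(self):
        g = nx.Graph()
        for i, j in itertools.combinations(range(5), 2):
            g.add_edge(("A", i), ("A", j), weight=0.2, absC=0.8)
        part = detect_communities(g)
        assert len(set(part.labels.values())) == 1

    def test_empty_network_rejected(self):
        with pytest.raises(AnalysisError):
            detect_communities(nx.Graph())

    def test_bridge_connectivity_counts_cross_pairs(self):
        g = self.two_cliques()
        part = detect_communities(g)
        counts = intercommunity_connectivity(g, part)
        # every cross-community node pair's shortest path crosses the bridge once
        assert sum(counts.values()) == 6 * 6

    def test_single_community_gives_empty_matrix(self):
        g = nx.Graph()
        for i, j in itertools.combinations(range(4), 2):
            g.add_edge(("A", i), ("A", j), weight=0.2, absC=0.8)
        part = detect_communities(g)
        assert intercommunity_connectivity(g, part) == {}


class TestPlantedRecovery:
    def test_two_block_ensemble_recovers_blocks(self):
        """End-to-end: sampled two-block ensemble -> contacts -> weights ->
        Girvan-Newman recovers the planted split (up to label permutation)."""
        spec, truth, _ = community_study_spec(n_receptor_residues=16, n_frames=500, seed=13)
        ens, truth = allodyn.sample_ensemble(spec, truth)
        fitted = allodyn.superpose(ens, spec.reference, "chain A and name CA")
        cm = contact_occupancy(fitted, "chain A")
        corr = allodyn.dccm(fitted, "chain A and name CA")
        g = weight_edges(cm, corr)
        part = detect_communities(g)
        found = {}
        for (ch, rid), lab in part.labels.items():
            found.setdefault(lab, set()).add(rid)
        planted = {}
        for rid, lab in truth.community_labels.items():
            planted.setdefault(lab, set()).add(rid)
        assert {frozenset(v) for v in found.values()} == {frozenset(v) for v in planted.values()}

    def test_planted_chain_is_the_optimal_path(self, path_fixture):
        fitted, truth, _, _ = path_fixture
        cm = contact_occupancy(fitted, "chain A")
        corr = allodyn.dccm(fitted, "chain A and name CA")
        g = weight_edges(cm, corr)
        p = optimal_path(g, truth.source, truth.target)
        assert p.reachable
        assert [n[1] for n in p.nodes] == truth.chain_residues
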