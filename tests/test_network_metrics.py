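"""Centralities, efficiencies, folding degree, paths and partitions.

The heavier checks compare against exhaustive or independently coded oracles:
brute-force shortest-path enumeration for betweenness and paths, an
independent scipy-based efficiency computation for the efficiency measures,
and full partition enumeration for modularity on six nodes.
"""

import itertools

import networkx as nx
import numpy as np
import pytest
from scipy.sparse.csgraph import dijkstra
from scipy.spatial.transform import Rotation

from prnkit import (
    efficiency_centrality,
    folding_degree,
    global_efficiency,
    local_efficiency,
    louvain_communities,
    node_centrality,
    shortest_path,
    spectral_partition,
    total_energy_centrality,
)
from prnkit.network_metrics import NoPathError

from conftest import backbone_structure, chain_from_dihedrals


def weighted_graph(edges):
    g = nx.Graph()
    for u, v, w in edges:
        g.add_edge(u, v, weight=w, importance=1.0 / w)
    return g


def random_graph(seed, n_max=6):
    rng = np.random.default_rng(seed)
    n = rng.integers(3, n_max + 1)
    g = nx.Graph()
    g.add_nodes_from(range(n))
    for i in range(n):
        for j in range(i + 1, n):
            if rng.random() < 0.6:
                # weights are multiples of 1/8 so path-length ties are exact in floats
                w = float(rng.integers(2, 17)) / 8.0
                g.add_edge(i, j, weight=w, importance=1.0 / w)
    return g


# ---------------------------------------------------------------- oracles


def all_min_weight_paths(g, s, t):
    """Exhaustive enumeration of minimal-total-weight simple paths."""
    best, best_len = [], np.inf
    for path in nx.all_simple_paths(g, s, t):
        length = sum(g[u][v]["weight"] for u, v in zip(path, path[1:]))
        if length < best_len:
            best, best_len = [path], length
        elif length == best_len:
            best.append(path)
    return best, best_len


def brute_force_betweenness(g):
    """Normalized betweenness from explicit shortest-path enumeration."""
    nodes = list(g.nodes)
    n = len(nodes)
    scores = {v: 0.0 for v in nodes}
    for s, t in itertools.combinations(nodes, 2):
        try:
            paths, _ = all_min_weight_paths(g, s, t)
        except nx.NetworkXNoPath:
            continue
        if not paths:
            continue
        for v in nodes:
            if v in (s, t):
                continue
            through = sum(1 for p in paths if v in p)
            scores[v] += through / len(paths)
    norm = 2.0 / ((n - 1) * (n - 2)) if n > 2 else 1.0
    return {v: s * norm for v, s in scores.items()}


def scipy_global_efficiency(g):
    """Independent weighted efficiency via scipy's dijkstra."""
    nodes = list(g.nodes)
    n = len(nodes)
    mat = nx.to_scipy_sparse_array(g, nodelist=nodes, weight="weight")
    d = dijkstra(mat, directed=False)
    inv = np.where((d > 0) & np.isfinite(d), 1.0 / np.where(d > 0, d, 1), 0.0)
    return inv.sum() / (n * (n - 1))


# ---------------------------------------------------------------- tests


class TestNodeCentrality:
    def test_star_hub_degree(self):
        g = weighted_graph([("h", f"l{i}", 1.0) for i in range(3)])
        res = node_centrality(g, "degree")
        assert res.values["h"] == pytest.approx(1.0)

    def test_path_middle_betweenness(self):
        g = weighted_graph([("a", "b", 1.0), ("b", "c", 1.0)])
        res = node_centrality(g, "betweenness")
        assert res.values["b"] == pytest.approx(1.0)

    @pytest.mark.parametrize("seed", range(8))
    def test_betweenness_matches_exhaustive_enumeration(self, seed):
        g = random_graph(seed)
        res = node_centrality(g, "betweenness")
        oracle = brute_force_betweenness(g)
        for v in g.nodes:
            assert res.values[v] == pytest.approx(oracle[v], abs=1e-9)

    def test_closeness_disconnected_scaling(self):
        g = weighted_graph([("a", "b", 1.0)])
        g.add_node("c")
        res = node_centrality(g, "closeness")
        # component of size 2 in a 3-node graph: scaled by (2−1)/(3−1)
        assert res.values["a"] == pytest.approx(0.5)
        assert res.values["c"] == 0.0

    def test_current_flow_runs_per_component(self):
        g = weighted_graph([("a", "b", 1.0), ("b", "c", 1.0), ("x", "y", 1.0)])
        res = node_centrality(g, "current_flow_betweenness")
        assert set(res.values) == {"a", "b", "c", "x", "y"}
        assert res.values["b"] >= res.values["a"]

    def test_permutation_equivariance(self):
        g = random_graph(42)
        res = node_centrality(g, "betweenness")
        mapping = {n: f"node_{n}" for n in g.nodes}
        res2 = node_centrality(nx.relabel_nodes(g, mapping), "betweenness")
        for n in g.nodes:
            assert res2.values[mapping[n]] == pytest.approx(res.values[n])

    def test_empty_graph_rejected(self):
        with pytest.raises(ValueError):
            node_centrality(nx.Graph(), "degree")


class TestTotalEnergyCentrality:
    def test_sums_adjacent_energies(self):
        g = nx.Graph()
        g.add_edge("k", "a", e_tot=-3.0, weight=1 / 3, importance=3.0)
        g.add_edge("k", "b", e_tot=-2.5, weight=1 / 2.5, importance=2.5)
        g.add_node("iso")
        res = total_energy_centrality(g)
        assert res.values["k"] == pytest.approx(-5.5)
        assert res.values["iso"] == 0.0

    def test_handshake_identity(self):
        rng = np.random.default_rng(4)
        g = random_graph(4)
        for u, v in g.edges:
            g[u][v]["e_tot"] = float(rng.normal(-3, 1))
        res = total_energy_centrality(g)
        assert sum(res.values.values()) == pytest.approx(
            2 * sum(d["e_tot"] for _, _, d in g.edges(data=True))
        )

    def test_distance_network_rejected(self):
        g = nx.Graph(kind="dprn")
        g.add_edge("a", "b", weight=5.0, importance=0.2)
        with pytest.raises(ValueError):
            total_energy_centrality(g)


class TestEfficiency:
    def test_path_of_three(self):
        g = weighted_graph([("a", "b", 1.0), ("b", "c", 1.0)])
        assert global_efficiency(g) == pytest.approx(5 / 6)

    def test_complete_graph_is_one(self):
        g = weighted_graph(
            [(i, j, 1.0) for i, j in itertools.combinations(range(4), 2)]
        )
        assert global_efficiency(g) == pytest.approx(1.0)

    def test_isolated_pair_is_zero(self):
        g = nx.Graph()
        g.add_nodes_from(["a", "b"])
        assert global_efficiency(g) == 0.0

    def test_local_efficiency_of_clique_member(self):
        g = weighted_graph(
            [(i, j, 1.0) for i, j in itertools.combinations(range(4), 2)]
        )
        assert local_efficiency(g, 0) == pytest.approx(1.0)

    def test_star_hub_efficiency_centrality(self):
        g = weighted_graph([("h", f"l{i}", 1.0) for i in range(3)])
        res = efficiency_centrality(g)
        assert res.values["h"] == pytest.approx(1.0)
        assert res.values["l0"] == pytest.approx((0.75 - 5 / 6) / 0.75)

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_remove_and_recompute_oracle(self, seed):
        g = random_graph(seed, n_max=8)
        res = efficiency_centrality(g)
        e_full = scipy_global_efficiency(g)
        for k in g.nodes:
            rest = g.subgraph([n for n in g.nodes if n != k])
            expected = (e_full - scipy_global_efficiency(rest)) / e_full
            assert res.values[k] == pytest.approx(expected, abs=1e-9)

    def test_complete_graph_symmetry(self):
        g = weighted_graph(
            [(i, j, 1.0) for i, j in itertools.combinations(range(5), 2)]
        )
        res = efficiency_centrality(g)
        vals = list(res.values.values())
        assert max(vals) - min(vals) < 1e-12


class TestFoldingDegree:
    def test_rigid_motion_invariance(self):
        coords = chain_from_dihedrals([-57, -47, 180] * 4)
        s = backbone_structure(coords)
        base = folding_degree(s)
        rot = Rotation.from_euler("xyz", [0.3, -1.1, 2.0]).as_matrix()
        moved = backbone_structure(coords @ rot.T + np.array([5.0, -2.0, 8.0]))
        transformed = folding_degree(moved)
        for k in base:
            assert transformed[k] == pytest.approx(base[k], abs=1e-8)

    def test_short_chain_rejected(self):
        s = backbone_structure(chain_from_dihedrals([]))  # 3 atoms only
        with pytest.raises(ValueError):
            folding_degree(s)

    def test_helix_scores_above_extended_strand(self):
        helix = backbone_structure(chain_from_dihedrals([-57, -47, 180] * 6))
        strand = backbone_structure(chain_from_dihedrals([-135, 135, 180] * 6))
        h = np.mean(list(folding_degree(helix).values()))
        e = np.mean(list(folding_degree(strand).values()))
        assert h > e


class TestShortestPath:
    def test_detour_beats_direct_edge(self):
        g = weighted_graph([("s", "t", 1.0), ("s", "m", 0.4), ("m", "t", 0.4)])
        path, length = shortest_path(g, "s", "t")
        assert path == ["s", "m", "t"]
        assert length == pytest.approx(0.8)

    def test_disconnected_raises(self):
        g = nx.Graph()
        g.add_nodes_from(["s", "t"])
        with pytest.raises(NoPathError):
            shortest_path(g, "s", "t")

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_exhaustive_enumeration(self, seed):
        g = random_graph(seed)
        nodes = sorted(g.nodes)
        s, t = nodes[0], nodes[-1]
        try:
            expected_paths, expected_len = all_min_weight_paths(g, s, t)
        except nx.NetworkXNoPath:
            expected_paths = []
        if not expected_paths:
            with pytest.raises(NoPathError):
                shortest_path(g, s, t)
            return
        path, length = shortest_path(g, s, t)
        assert length == pytest.approx(expected_len)
        assert path == min(expected_paths)


class TestPartitions:
    def two_cliques_bridge(self):
        g = nx.Graph()
        for base in (0, 3):
            for i, j in itertools.combinations(range(base, base + 3), 2):
                g.add_edge(i, j, weight=1.0, importance=1.0)
        g.add_edge(2, 3, weight=1.0, importance=1.0)
        return g

    def brute_force_best_modularity(self, g):
        nodes = sorted(g.nodes)

        def partitions(seq):
            if not seq:
                yield []
                return
            head, rest = seq[0], seq[1:]
            for p in partitions(rest):
                for i in range(len(p)):
                    yield p[:i] + [p[i] + [head]] + p[i + 1 :]
                yield p + [[head]]

        best, best_q = None, -np.inf
        for p in partitions(nodes):
            q = nx.community.modularity(g, [set(c) for c in p], weight="importance")
            if q > best_q:
                best, best_q = p, q
        return {frozenset(c) for c in best}, best_q

    def test_edgeless_graph_gives_singletons(self):
        g = nx.Graph()
        g.add_nodes_from("abc")
        part = louvain_communities(g, seed=1)
        assert part.n_communities == 3

    def test_louvain_recovers_planted_cliques(self):
        g = self.two_cliques_bridge()
        part = louvain_communities(g, seed=0)
        expected, best_q = self.brute_force_best_modularity(g)
        assert {frozenset(c) for c in part.communities()} == expected
        assert part.modularity == pytest.approx(best_q)

    def test_modularity_beats_singleton_partition(self):
        g = self.two_cliques_bridge()
        part = louvain_communities(g, seed=0)
        singleton_q = nx.community.modularity(
            g, [{n} for n in g.nodes], weight="importance"
        )
        assert part.modularity >= singleton_q

    def test_same_seed_same_partition(self):
        g = random_graph(9, n_max=12)
        p1 = louvain_communities(g, seed=7)
        p2 = louvain_communities(g, seed=7)
        assert p1.assignment == p2.assignment

    def test_spectral_trivial_k(self):
        g = self.two_cliques_bridge()
        assert spectral_partition(g, 1).n_communities == 1
        part_n = spectral_partition(g, g.number_of_nodes())
        assert part_n.n_communities == g.number_of_nodes()

    def test_spectral_splits_cliques(self):
        g = self.two_cliques_bridge()
        part = spectral_partition(g, 2, seed=0)
        comms = {frozenset(c) for c in part.communities()}
        assert comms == {frozenset({0, 1, 2}), frozenset({3, 4, 5})}

    def test_spectral_k_out_of_range(self):
        g = self.two_cliques_bridge()
        with pytest.raises(ValueError):
            spectral_partition(g, 7)

    def test_assignment_covers_every_node_once(self, toy_split):
        split, _, _ = toy_split
        part = louvain_communities(split.g, seed=3)
        assert set(part.assignment) == set(split.g.nodes)
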