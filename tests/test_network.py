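"""First-shell expansion, centralities and HBS classification."""

import itertools

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from pancanet import network as net
from pancanet.core import InvalidParameterError


def edge_frame(edges):
    return pd.DataFrame(edges, columns=["node_a", "node_b", "confidence"])


def brute_force_betweenness(g: nx.Graph) -> dict:
    """Independent oracle: enumerate every simple path between each pair,
    keep the shortest ones, and accumulate fractional interior counts."""
    bc = {v: 0.0 for v in g.nodes}
    for s, t in itertools.combinations(list(g.nodes), 2):
        paths = []

        def dfs(u, visited, path):
            if u == t:
                paths.append(list(path))
                return
            for w in g[u]:
                if w not in visited:
                    visited.add(w)
                    path.append(w)
                    dfs(w, visited, path)
                    path.pop()
                    visited.remove(w)

        dfs(s, {s}, [s])
        if not paths:
            continue
        shortest = min(len(p) for p in paths)
        sp = [p for p in paths if len(p) == shortest]
        for p in sp:
            for v in p[1:-1]:
                bc[v] += 1.0 / len(sp)
    return bc


class TestExpandFirstShell:
    def test_zero_interactors_keeps_seeds_only(self):
        edges = edge_frame([("s1", "s2", 0.9), ("s1", "x", 0.9), ("s2", "y", 0.9)])
        g = net.expand_first_shell(["s1", "s2"], edges, max_interactors=0)
        assert set(g.nodes) == {"s1", "s2"}
        assert g.has_edge("s1", "s2")

    def test_confidence_boundary_inclusive(self):
        edges = edge_frame([("s1", "x", 0.39), ("s1", "y", 0.40)])
        g = net.expand_first_shell(["s1"], edges)
        assert "y" in g.nodes and "x" not in g.nodes

    def test_interactor_cap(self):
        edges = [("s1", f"a{i:03d}", 0.9) for i in range(150)]
        edges += [("s2", f"b{i:03d}", 0.9) for i in range(150)]
        g = net.expand_first_shell(["s1", "s2"], edge_frame(edges))
        interactors = [n for n in g.nodes if not g.nodes[n]["is_seed"]]
        assert len(interactors) == 200

    def test_cap_prefers_multi_seed_neighbors(self):
        edges = [("s1", "both", 0.5), ("s2", "both", 0.5),
                 ("s1", "strong", 0.9), ("s1", "weak", 0.45)]
        g = net.expand_first_shell(["s1", "s2"], edge_frame(edges), max_interactors=2)
        kept = {n for n in g.nodes if not g.nodes[n]["is_seed"]}
        assert kept == {"both", "strong"}

    def test_absent_seed_reported_unconnected(self):
        edges = edge_frame([("s1", "x", 0.9)])
        g = net.expand_first_shell(["s1", "ghost"], edges)
        assert g.graph["unconnected_seeds"] == ["ghost"]
        assert "ghost" not in g.nodes

    def test_empty_interactome_warns_and_isolates(self):
        with pytest.warns(UserWarning):
            g = net.expand_first_shell(["s1", "s2"], edge_frame([]))
        assert set(g.nodes) == {"s1", "s2"} and g.number_of_edges() == 0

    def test_empty_seeds_rejected(self):
        with pytest.raises(InvalidParameterError):
            net.expand_first_shell([], edge_frame([("a", "b", 0.9)]))


class TestCentralities:
    def test_path_graph_hand_values(self, path_graph):
        prof = net.centralities(path_graph)
        assert prof.degree["b"] == 2 and prof.degree["a"] == 1
        assert prof.betweenness["b"] == pytest.approx(1.0)  # single a-c path
        assert prof.betweenness["a"] == 0.0

    def test_star_center_dominates_eigenvector(self, star_graph):
        prof = net.centralities(star_graph)
        assert prof.eigenvector["c"] > prof.eigenvector["a"]

    def test_edgeless_graph_all_zero(self):
        g = nx.empty_graph(["a", "b", "c"])
        prof = net.centralities(g)
        assert set(prof.degree.values()) == {0}
        assert set(prof.betweenness.values()) == {0.0}
        assert set(prof.eigenvector.values()) == {0.0}

    def test_betweenness_matches_brute_force(self):
        rng = np.random.default_rng(42)
        for _ in range(30):
            n = int(rng.integers(3, 9))
            g = nx.gnp_random_graph(n, float(rng.uniform(0.2, 0.9)),
                                    seed=int(rng.integers(0, 10**6)))
            prof = net.centralities(g)
            oracle = brute_force_betweenness(g)
            for v in g.nodes:
                assert prof.betweenness[v] == pytest.approx(oracle[v], abs=1e-9)

    def test_eigenvector_matches_networkx(self):
        g = nx.gnp_random_graph(25, 0.2, seed=7)
        g = g.subgraph(max(nx.connected_components(g), key=len)).copy()
        prof = net.centralities(g)
        ref = nx.eigenvector_centrality_numpy(g)
        norm = np.linalg.norm(list(ref.values()))
        for v in g.nodes:
            assert prof.eigenvector[v] == pytest.approx(abs(ref[v]) / norm, abs=1e-6)

    def test_eigen_equation_residual(self, star_graph):
        prof = net.centralities(star_graph)
        nodes = sorted(star_graph.nodes)
        a = nx.to_numpy_array(star_graph, nodelist=nodes)
        v = np.array([prof.eigenvector[n] for n in nodes])
        lam = v @ a @ v
        assert np.abs(a @ v - lam * v).max() < 1e-8


class TestClassify:
    def test_star_center_hbs_leaves_ntr(self, star_graph):
        prof = net.centralities(star_graph)
        labels = net.classify_hbs(prof, list(star_graph.nodes), star_graph)
        assert labels["c"] == "HBS"
        assert labels["a"] == "NTR"

    def test_absent_seed_is_na(self, star_graph):
        prof = net.centralities(star_graph)
        labels = net.classify_hbs(prof, ["c", "GHOST"], star_graph)
        assert labels["GHOST"] == "NA"

    def test_cycle_is_all_ntr(self):
        g = nx.cycle_graph(6)
        labels = net.topology_labels(net.centralities(g))
        assert set(labels.values()) == {"NTR"}

    def test_planted_hub_labeled_hub(self):
        """The synthetic interactome's boosted node earns an H label."""
        from pancanet import synth
        wins = 0
        for seed in range(40):
            edges = synth.gen_interactome(
                80, planted_hubs=["P0040"], background_edge_prob=0.03,
                hub_degree_boost=25, seed=seed)
            g = nx.Graph()
            for a, b, c in edges.itertuples(index=False):
                g.add_edge(a, b, confidence=c)
            labels = net.topology_labels(net.centralities(g))
            wins += "H" in labels.get("P0040", "")
        assert wins >= 38


class TestHbsSubnetwork:
    def test_all_hbs_returns_whole_network(self, star_graph):
        labels = {n: "HBS" for n in star_graph.nodes}
        sub = net.extract_hbs_subnetwork(star_graph, labels)
        assert set(sub.nodes) == set(star_graph.nodes)
        assert sub.number_of_edges() == star_graph.number_of_edges()

    def test_star_yields_isolated_center(self, star_graph):
        labels = net.topology_labels(net.centralities(star_graph))
        sub = net.extract_hbs_subnetwork(star_graph, labels)
        assert set(sub.nodes) == {"c"} and sub.number_of_edges() == 0

    def test_induced_edges_only_among_hbs(self):
        g = nx.Graph([("a", "b"), ("b", "c"), ("a", "c"), ("a", "d")])
        labels = {"a": "HBS", "b": "HBS", "c": "H", "d": "HBS"}
        sub = net.extract_hbs_subnetwork(g, labels)
        assert set(sub.edges) == {("a", "b"), ("a", "d")}

    def test_no_hbs_warns_empty(self, star_graph):
        with pytest.warns(UserWarning):
            sub = net.extract_hbs_subnetwork(star_graph, {n: "NTR" for n in star_graph})
        assert sub.number_of_nodes() == 0
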