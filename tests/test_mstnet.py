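"""Correlation graph, sparsification, Prim MST, communities, centralities."""

import itertools

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from coexnet import mstnet
from coexnet.simulate import generate_graph_fixture

from conftest import make_frame


def brute_force_mst_weight(g: nx.Graph, weight_mode: str) -> float:
    """Enumerate every spanning tree; return the minimum total edge key."""
    nodes = list(g.nodes)
    edges = list(g.edges(data=True))
    best = np.inf
    for combo in itertools.combinations(edges, len(nodes) - 1):
        t = nx.Graph()
        t.add_nodes_from(nodes)
        t.add_edges_from([(u, v) for u, v, _ in combo])
        if nx.is_connected(t):
            key = sum(
                d["weight"] if weight_mode == "signed" else 1 - abs(d["weight"])
                for _, _, d in combo
            )
            best = min(best, key)
    return best


def kruskal_total_key(g: nx.Graph, weight_mode: str) -> float:
    """Independent Kruskal implementation (union-find over sorted keys)."""
    parent = {n: n for n in g.nodes}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def key(d):
        return d["weight"] if weight_mode == "signed" else 1 - abs(d["weight"])

    total = 0.0
    for u, v, d in sorted(g.edges(data=True), key=lambda e: key(e[2])):
        ru, rv = find(u), find(v)
        if ru != rv:
            parent[ru] = rv
            total += key(d)
    return total


def random_weighted_graph(rng, n, p=0.6):
    g = nx.gnp_random_graph(n, p, seed=int(rng.integers(2**31)))
    while not nx.is_connected(g) or g.number_of_nodes() < n:
        g = nx.gnp_random_graph(n, p, seed=int(rng.integers(2**31)))
    for u, v in g.edges:
        g[u][v]["weight"] = float(rng.uniform(-1, 1))
    return g


class TestCorrelationNetwork:
    def test_diagonal_and_antisymmetry(self, rng):
        x = rng.standard_normal(30)
        X = make_frame(np.vstack([x, -x + 1e-12 * rng.standard_normal(30)]))
        C = mstnet.correlation_network(X, "spearman")
        assert C.iloc[0, 0] == pytest.approx(1.0)
        assert C.iloc[0, 1] == pytest.approx(-1.0)

    def test_monotone_transform_distinguishes_methods(self, rng):
        x = rng.standard_normal(50)
        X = make_frame(np.vstack([x, np.exp(x)]))
        sp = mstnet.correlation_network(X, "spearman")
        pe = mstnet.correlation_network(X, "pearson")
        assert sp.iloc[0, 1] == pytest.approx(1.0)
        assert pe.iloc[0, 1] < 1.0

    def test_zero_variance_rejected(self, rng):
        X = make_frame(np.vstack([rng.standard_normal(10), np.ones(10)]))
        with pytest.raises(ValueError, match="zero-variance"):
            mstnet.correlation_network(X)


class TestSparsify:
    def _net(self, w):
        genes = sorted({g for pair in w for g in pair})
        C = pd.DataFrame(np.eye(len(genes)), index=genes, columns=genes)
        for (a, b), v in w.items():
            C.loc[a, b] = C.loc[b, a] = v
        return C

    def test_worked_tail_rule(self):
        C = self._net({("A", "B"): 0.9, ("A", "C"): 0.5, ("B", "C"): -0.8})
        g = mstnet.sparsify_network(C, f=0.8)  # cutoffs 0.72 / -0.64
        assert sorted(map(tuple, map(sorted, g.edges))) == [("A", "B"), ("B", "C")]
        assert set(g.nodes) == {"A", "B", "C"}

    def test_largest_component_kept(self):
        w = {("A", "B"): 0.9, ("B", "C"): 0.9, ("C", "D"): 0.9, ("D", "E"): 0.9,
             ("X", "Y"): 0.9, ("Y", "Z"): 0.9}
        C = self._net(w)
        g = mstnet.sparsify_network(C, f=0.8)
        assert set(g.nodes) == {"A", "B", "C", "D", "E"}

    def test_f_near_one_keeps_only_extremes(self):
        C = self._net({("A", "B"): 0.9, ("A", "C"): 0.5, ("B", "C"): -0.8})
        g = mstnet.sparsify_network(C, f=0.999)
        # only the max-positive and min-negative edges survive
        assert sorted(map(tuple, map(sorted, g.edges))) == [("A", "B"), ("B", "C")]

    def test_invalid_fraction(self):
        C = self._net({("A", "B"): 0.5})
        with pytest.raises(ValueError):
            mstnet.sparsify_network(C, f=1.0)


class TestMstPrim:
    def triangle(self):
        g = nx.Graph()
        g.add_edge("A", "B", weight=-0.9)
        g.add_edge("B", "C", weight=-0.8)
        g.add_edge("A", "C", weight=0.95)
        return g

    def test_triangle_signed_vs_absolute(self):
        # frozen from exhaustive enumeration of the three spanning trees
        t = mstnet.mst_prim(self.triangle(), "signed")
        assert sorted(map(tuple, map(sorted, t.edges))) == [("A", "B"), ("B", "C")]
        assert t.total_weight == pytest.approx(-1.7)
        t2 = mstnet.mst_prim(self.triangle(), "absolute")
        assert sorted(map(tuple, map(sorted, t2.edges))) == [("A", "B"), ("A", "C")]

    def test_tree_shape_and_acyclicity(self, rng):
        g = random_weighted_graph(rng, 20)
        t = mstnet.mst_prim(g)
        assert t.graph.number_of_edges() == 19
        assert nx.is_tree(t.graph)

    def test_equal_weights_deterministic(self):
        g = nx.complete_graph(5)
        nx.set_edge_attributes(g, 1.0, "weight")
        t1 = mstnet.mst_prim(g)
        t2 = mstnet.mst_prim(g)
        assert sorted(t1.edges) == sorted(t2.edges)
        assert all(0 in e for e in t1.edges)  # lexicographic star from node 0

    @pytest.mark.parametrize("mode", ["signed", "absolute"])
    def test_matches_exhaustive_enumeration_small(self, mode, rng):
        for _ in range(25):
            g = random_weighted_graph(rng, int(rng.integers(4, 8)))
            t = mstnet.mst_prim(g, mode)
            key = sum(
                d["weight"] if mode == "signed" else 1 - abs(d["weight"])
                for _, _, d in t.graph.edges(data=True)
            )
            assert key == pytest.approx(brute_force_mst_weight(g, mode))

    def test_matches_independent_kruskal(self, rng):
        for _ in range(10):
            g = random_weighted_graph(rng, 50, p=0.2)
            t = mstnet.mst_prim(g, "signed")
            assert t.total_weight == pytest.approx(kruskal_total_key(g, "signed"))

    def test_disconnected_rejected(self):
        g = nx.Graph()
        g.add_edge("A", "B", weight=1.0)
        g.add_node("C")
        with pytest.raises(ValueError, match="disconnected"):
            mstnet.mst_prim(g)


class TestCommunities:
    def test_two_cliques_bridge_recovered_by_both_methods(self):
        g = generate_graph_fixture("two_cliques_bridge", 4)
        for method in ("edge_betweenness", "louvain"):
            part = mstnet.detect_communities(g, method, seed=0)
            assert part.n_communities == 2
            assert part.members(1) in ([0, 1, 2, 3], [4, 5, 6, 7])
        # the bridge carries the maximum edge betweenness
        eb = nx.edge_betweenness_centrality(g)
        assert max(eb, key=eb.get) in ((3, 4), (4, 3))

    def test_two_node_path(self):
        g = nx.path_graph(2)
        part = mstnet.detect_communities(g, "louvain", seed=0)
        assert set(part.labels.values()) <= {1, 2}
        assert part.modularity <= 0

    def test_louvain_deterministic_under_seed(self, rng):
        g = random_weighted_graph(rng, 40, p=0.15)
        a = mstnet.detect_communities(g, "louvain", seed=5)
        b = mstnet.detect_communities(g, "louvain", seed=5)
        assert a.labels == b.labels

    def test_single_node_rejected(self):
        g = nx.Graph()
        g.add_node("A")
        with pytest.raises(ValueError):
            mstnet.detect_communities(g, "louvain", seed=0)


class TestCentralities:
    def test_path_hand_values(self):
        g = nx.Graph()
        g.add_edge("A", "B", weight=1.0)
        g.add_edge("B", "C", weight=1.0)
        tab = mstnet.compute_centralities(g)
        assert tab.loc["B", "degree"] == 2
        assert tab.loc["B", "betweenness"] == 1
        assert tab.loc["A", "betweenness"] == 0
        assert tab.loc["B", "closeness"] == pytest.approx(1.0)
        assert tab.loc["A", "closeness"] == pytest.approx(2 / 3)

    def test_star_closed_form(self):
        n = 11
        g = nx.star_graph(n - 1)
        nx.set_edge_attributes(g, 1.0, "weight")
        tab = mstnet.compute_centralities(g)
        assert tab.loc[0, "betweenness"] == (n - 1) * (n - 2) / 2
        assert tab.loc[0, "closeness"] == pytest.approx(1.0)

    def test_scaled_columns_span_unit_interval(self, rng):
        g = random_weighted_graph(rng, 30, p=0.2)
        t = mstnet.mst_prim(g)
        tab = mstnet.compute_centralities(t)
        for m in mstnet.MEASURES:
            col = tab[f"{m}_scaled"]
            assert col.min() == 0.0 and col.max() == 1.0

    def test_tree_betweenness_pair_identity(self, rng):
        # on a tree, total betweenness equals sum over pairs of
        # (path length - 1) since every pair's unique path is shortest
        g = random_weighted_graph(rng, 25)
        t = mstnet.mst_prim(g).graph
        tab = mstnet.compute_centralities(t)
        lengths = dict(nx.all_pairs_shortest_path_length(t))
        expect = sum(
            lengths[u][v] - 1
            for u in t.nodes for v in t.nodes if str(u) < str(v)
        )
        assert tab["betweenness"].sum() == pytest.approx(expect)

    def test_representatives_take_community_maximum(self):
        g = generate_graph_fixture("two_cliques_bridge", 4)
        part = mstnet.detect_communities(g, "louvain", seed=0)
        tab = mstnet.compute_centralities(g, part)
        for cid in (1, 2):
            sub = tab[tab["community"] == cid]
            rep = sub[sub["degree_representative"]]
            assert rep["degree"].iloc[0] == sub["degree"].max()


class TestDifferentialCentrality:
    @staticmethod
    def _table(vals):
        cols = [f"{m}_scaled" for m in mstnet.MEASURES]
        return pd.DataFrame({c: vals for c in cols},
                            index=[f"g{i}" for i in range(len(vals))])

    def test_rule_arithmetic(self):
        ctrl = self._table([0.1, 0.9])
        case = self._table([1.0, 0.9])
        out = mstnet.differential_centrality(ctrl, case)
        assert out.loc["g0", "composite_delta"] == pytest.approx(0.9)
        assert out.loc["g0", "class"] == "pathology_specific"
        assert out.loc["g1", "class"] == "shared_central"

    def test_absent_gene_scores_zero_in_missing_tree(self):
        ctrl = self._table([0.2])
        case = self._table([0.8, 0.8])  # g1 absent from control
        out = mstnet.differential_centrality(ctrl, case)
        assert out.loc["g1", "composite_control"] == 0.0
        assert out.loc["g1", "class"] == "pathology_specific"

    def test_sorted_by_descending_composite_delta(self):
        ctrl = self._table([0.5, 0.0, 0.9])
        case = self._table([0.6, 0.9, 0.1])
        out = mstnet.differential_centrality(ctrl, case)
        assert list(out["composite_delta"]) == sorted(
            out["composite_delta"], reverse=True
        )

    def test_empty_tables_rejected(self):
        with pytest.raises(ValueError):
            mstnet.differential_centrality(pd.DataFrame(), self._table([0.5]))
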