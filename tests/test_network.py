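"""Network screening: centralities vs independent oracles, decile overlap,
cluster metrics and filtering, target intersection."""

import math

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from aconiqstr.network import (
    ClusterMetrics,
    as_graph,
    betweenness_centrality,
    centrality_table,
    closeness_centrality,
    cluster_metrics,
    filter_clusters,
    intersect_targets,
    read_edge_list,
    subgraph_centrality,
    top_decile,
    top_decile_overlap,
)
from aconiqstr.synthetic import gen_ba_network


def series_subgraph_centrality(graph, terms=30):
    """Independent oracle: truncated series sum_l diag(A^l)/l!."""
    A = nx.to_numpy_array(graph, weight=None)
    acc = np.zeros(len(A))
    power = np.eye(len(A))
    for l in range(terms):
        acc += np.diag(power) / math.factorial(l)
        power = power @ A
    return dict(zip(graph.nodes(), acc))


def brute_force_betweenness(graph):
    """Independent oracle: shortest-path counts by distance-matrix DP."""
    nodes = list(graph.nodes())
    idx = {u: i for i, u in enumerate(nodes)}
    n = len(nodes)
    INF = float("inf")
    dist = np.full((n, n), INF)
    sigma = np.zeros((n, n))
    np.fill_diagonal(dist, 0.0)
    np.fill_diagonal(sigma, 1.0)
    for u, v in graph.edges():
        dist[idx[u], idx[v]] = dist[idx[v], idx[u]] = 1.0
    for k in range(n):  # Floyd-Warshall distances
        dist = np.minimum(dist, dist[:, k:k + 1] + dist[k:k + 1, :])
    order = sorted(((dist[s, t], s, t) for s in range(n) for t in range(n)
                    if s != t and np.isfinite(dist[s, t])))
    for d, s, t in order:  # path counts in increasing distance
        if d == 1.0:
            sigma[s, t] = 1.0
            continue
        sigma[s, t] = sum(sigma[s, w] for w in range(n)
                          if dist[s, w] + 1.0 == d and dist[w, t] == 1.0)
    cb = {}
    for ui, u in enumerate(nodes):
        total = 0.0
        for s in range(n):
            for t in range(s + 1, n):
                if s == ui or t == ui or not np.isfinite(dist[s, t]):
                    continue
                if dist[s, ui] + dist[ui, t] == dist[s, t] and sigma[s, t] > 0:
                    total += sigma[s, ui] * sigma[ui, t] / sigma[s, t]
        cb[u] = total
    return cb


class TestSubgraphCentrality:
    def test_isolated_node_scores_one(self):
        g = nx.Graph()
        g.add_node("lonely")
        g.add_edge("a", "b")
        cs = subgraph_centrality(g)
        assert cs["lonely"] == pytest.approx(1.0, abs=1e-12)

    def test_single_edge_cosh(self):
        g = nx.Graph([("a", "b")])
        cs = subgraph_centrality(g)
        assert cs["a"] == pytest.approx(math.cosh(1.0), abs=1e-10)
        assert cs["b"] == pytest.approx(math.cosh(1.0), abs=1e-10)

    def test_triangle_closed_form(self):
        g = nx.complete_graph(3)
        expected = math.e**2 / 3 + 2 / (3 * math.e)
        for v in subgraph_centrality(g).values():
            assert v == pytest.approx(expected, abs=1e-10)

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_series_oracle(self, seed):
        rng = np.random.default_rng(seed)
        g = nx.gnp_random_graph(int(rng.integers(2, 13)), 0.4, seed=seed)
        ours = subgraph_centrality(g)
        oracle = series_subgraph_centrality(g)
        for u in g.nodes():
            assert ours[u] == pytest.approx(oracle[u], abs=1e-8)


class TestBetweenness:
    def test_path_graph_middle(self):
        cb = betweenness_centrality(nx.path_graph(3))
        assert cb[1] == pytest.approx(1.0)
        assert cb[0] == cb[2] == 0.0

    def test_star_center_counts_leaf_pairs(self):
        cb = betweenness_centrality(nx.star_graph(3))
        assert cb[0] == pytest.approx(3.0)

    def test_complete_graph_all_zero(self):
        assert all(v == 0.0 for v in betweenness_centrality(nx.complete_graph(5)).values())

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_enumeration_oracle(self, seed):
        rng = np.random.default_rng(100 + seed)
        g = nx.gnp_random_graph(int(rng.integers(3, 10)), 0.45, seed=seed)
        ours = betweenness_centrality(g)
        oracle = brute_force_betweenness(g)
        for u in g.nodes():
            assert ours[u] == pytest.approx(oracle[u], abs=1e-9)


class TestCloseness:
    def test_star_center_and_leaf(self):
        g = nx.star_graph(3)
        cc = closeness_centrality(g)
        assert cc[0] == pytest.approx(1.0)
        assert cc[1] == pytest.approx(3 / 5)

    def test_complete_graph_is_one(self):
        cc = closeness_centrality(nx.complete_graph(6))
        assert all(v == pytest.approx(1.0) for v in cc.values())

    def test_literal_variant_uses_neighbor_count(self):
        g = nx.star_graph(3)
        cc = closeness_centrality(g, variant="literal")
        assert cc[0] == pytest.approx((3 - 1) / 3)  # degree-1 over distance sum
        assert cc[1] == pytest.approx(0.0)          # leaf: (1-1)/5

    def test_singleton_component_zero(self):
        g = nx.Graph()
        g.add_node("x")
        g.add_edge("a", "b")
        assert closeness_centrality(g)["x"] == 0.0

    def test_disconnected_per_component(self):
        g = nx.disjoint_union(nx.complete_graph(3), nx.path_graph(3))
        cc = closeness_centrality(g)
        assert cc[0] == pytest.approx(1.0)
        assert cc[4] == pytest.approx(1.0)  # middle of the path component

    def test_unknown_variant_rejected(self):
        with pytest.raises(ValueError):
            closeness_centrality(nx.path_graph(3), variant="bogus")


def test_centralities_invariant_under_relabeling():
    g = gen_ba_network(40, 2, seed=5)
    mapping = {u: f"X{u}" for u in g.nodes()}
    h = nx.relabel_nodes(g, mapping)
    t_g = centrality_table(g)
    t_h = centrality_table(h)
    for m in ("subgraph", "betweenness", "closeness"):
        for u in g.nodes():
            assert t_g.loc[u, m] == pytest.approx(t_h.loc[mapping[u], m], rel=1e-9)


class TestTopDecile:
    def test_strict_winner_is_singleton(self):
        rng = np.random.default_rng(1)
        table = pd.DataFrame({
            "subgraph": rng.uniform(0, 1, 10),
            "betweenness": rng.uniform(0, 1, 10),
            "closeness": rng.uniform(0, 1, 10),
        }, index=[f"n{i}" for i in range(10)])
        table.loc["n3"] = 9.9
        assert top_decile_overlap(table) == {"n3"}

    def test_total_tie_includes_everyone(self):
        table = pd.DataFrame({m: np.ones(10) for m in ("subgraph", "betweenness", "closeness")},
                             index=[f"n{i}" for i in range(10)])
        assert top_decile_overlap(table) == set(table.index)

    def test_boundary_ties_included(self):
        s = pd.Series([5, 5, 5, 1, 1, 1, 1, 1, 1, 1], index=[f"n{i}" for i in range(10)])
        assert top_decile(s) == {"n0", "n1", "n2"}

    def test_pairwise_merge_is_superset(self):
        g = gen_ba_network(60, 3, seed=2)
        table = centrality_table(g)
        strict = top_decile_overlap(table, merge="intersection")
        loose = top_decile_overlap(table, merge="pairwise")
        assert strict <= loose

    def test_planted_hubs_recovered(self):
        g = gen_ba_network(100, 5, seed=3)
        overlap = top_decile_overlap(centrality_table(g))
        assert set(g.graph["hubs"]) <= overlap


class TestClusterMetrics:
    def test_triangle_is_perfect(self):
        g = nx.complete_graph(3)
        m = cluster_metrics(g, set(g.nodes()), n_perm=99, seed=0)
        assert m.density == 1.0
        assert m.quality == 1.0

    def test_independent_set_density_zero(self):
        g = nx.Graph()
        g.add_nodes_from(range(6))
        g.add_edge(0, 1)
        m = cluster_metrics(g, {2, 3, 4}, n_perm=99, seed=0)
        assert m.density == 0.0

    def test_planted_clique_significant(self):
        rng = np.random.default_rng(11)
        g = nx.gnp_random_graph(60, 0.04, seed=11)
        clique = list(range(54, 60))
        g.add_edges_from((u, v) for i, u in enumerate(clique) for v in clique[i + 1:])
        m = cluster_metrics(g, clique, n_perm=999, seed=11)
        assert m.p_value <= 0.01
        assert m.density == 1.0

    def test_small_cluster_rejected(self):
        with pytest.raises(ValueError):
            cluster_metrics(nx.complete_graph(4), {0}, n_perm=99, seed=0)

    def test_too_few_permutations_rejected(self):
        with pytest.raises(ValueError):
            cluster_metrics(nx.complete_graph(4), {0, 1}, n_perm=10, seed=0)

    def test_seeded_permutation_deterministic(self):
        g = nx.gnp_random_graph(30, 0.2, seed=3)
        a = cluster_metrics(g, {0, 1, 2, 3}, n_perm=199, seed=7)
        b = cluster_metrics(g, {0, 1, 2, 3}, n_perm=199, seed=7)
        assert a.p_value == b.p_value


class TestFilterClusters:
    def _metric(self, **kw):
        base = dict(members=frozenset({"a", "b", "c"}), size=3, density=0.6,
                    quality=0.7, p_value=0.01)
        base.update(kw)
        return ClusterMetrics(**base)

    def test_size_two_discarded(self):
        assert filter_clusters([self._metric(size=2, members=frozenset({"a", "b"}))]) == []

    def test_density_boundary(self):
        assert filter_clusters([self._metric(density=0.44)]) == []
        assert filter_clusters([self._metric(density=0.45)]) != []

    def test_quality_and_p_boundaries(self):
        assert filter_clusters([self._metric(quality=0.49)]) == []
        assert filter_clusters([self._metric(p_value=0.05)]) == []
        assert filter_clusters([self._metric(quality=0.5, p_value=0.049)]) != []


class TestIntersectTargets:
    def test_identical_singletons(self):
        lists = {"c1": pd.DataFrame({"protein": ["P1"], "score": [5.0]}),
                 "c2": pd.DataFrame({"protein": ["P1"], "score": [4.0]})}
        out = intersect_targets({"P1", "P2"}, lists)
        assert list(out["protein"]) == ["P1"]
        assert out["mean_score"].iloc[0] == pytest.approx(4.5)

    def test_disjoint_lists_empty(self):
        lists = {"c1": pd.DataFrame({"protein": ["P1"], "score": [1.0]}),
                 "c2": pd.DataFrame({"protein": ["P2"], "score": [1.0]})}
        assert len(intersect_targets({"P1", "P2"}, lists)) == 0

    def test_shared_proteins_ranked_by_mean_score(self):
        lists = {
            "c1": pd.DataFrame({"protein": ["A", "B", "C"], "score": [9, 5, 7]}),
            "c2": pd.DataFrame({"protein": ["A", "B", "D"], "score": [8, 6, 1]}),
            "c3": pd.DataFrame({"protein": ["A", "B"], "score": [7, 8]}),
        }
        out = intersect_targets({"A", "B"}, lists)
        assert list(out["protein"]) == ["A", "B"]
        assert out.attrs["unmapped"] == []

    def test_unmapped_ids_reported_not_fatal(self):
        lists = {"c1": pd.DataFrame({"protein": ["A", "Z"], "score": [1, 2]}),
                 "c2": pd.DataFrame({"protein": ["A", "Z"], "score": [1, 2]})}
        out = intersect_targets({"A"}, lists)
        assert list(out["protein"]) == ["A"]
        assert out.attrs["unmapped"] == ["Z"]


def test_self_loop_rejected():
    g = nx.Graph()
    g.add_edge("a", "a")
    with pytest.raises(ValueError, match="self-loop"):
        as_graph(g)


def test_edge_list_roundtrip(tmp_path):
    path = tmp_path / "edges.tsv"
    path.write_text("A\tB\t1.0\nB\tC\t0.5\nC\tC\t1.0\n")
    g = read_edge_list(path)
    assert set(g.edges()) == {("A", "B"), ("B", "C")}
    assert g["B"]["C"]["weight"] == 0.5
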