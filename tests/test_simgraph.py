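import itertools

import networkx as nx
import numpy as np
import pytest
from hypothesis import given, strategies as st

from actimood import (
    SimilarityGraphConfig,
    build_similarity_graph,
    graph_metrics,
    metrics_for_ks,
)


def brute_force_edges(x, cfg):
    """Edge set by a double loop over all node pairs (1-based)."""
    n = len(x)
    edges = set()
    for u in range(n):
        for v in range(u + 1, n):
            dist_ok = (v - u) < cfg.k if cfg.distance_comparator == "strict_less" else (v - u) <= cfg.k
            if not dist_ok:
                continue
            lo, hi = min(x[u], x[v]), max(x[u], x[v])
            if lo > 0:
                similar = hi / lo < cfg.ratio_threshold
            else:
                similar = hi == 0 and cfg.zero_pair_rule == "both_zero_similar"
            if similar:
                edges.add((u + 1, v + 1))
    return edges


def to_networkx(graph):
    g = nx.Graph()
    g.add_nodes_from(range(1, graph.n + 1))
    g.add_edges_from(graph.edges)
    return g


def random_series(rng, n):
    x = rng.gamma(2.0, 100.0, size=n)
    x[rng.random(n) < 0.05] = 0.0  # exercise the zero-pair rule
    return x


class TestWorkedExample:
    def test_eleven_point_series_metrics(self, fig1_series):
        graph = build_similarity_graph(fig1_series, SimilarityGraphConfig(k=5))
        gm = graph_metrics(graph)
        assert gm.edges_total == 13
        assert gm.components == 3
        assert gm.bridges == 2
        assert gm.missing_direct == 3
        assert gm.isolated == 1
        assert gm.triangles == 6
        assert gm.mean_edges == pytest.approx(26 / 11)

    def test_specific_edges(self, fig1_series):
        edges = build_similarity_graph(fig1_series, SimilarityGraphConfig(k=5)).edges
        assert (1, 4) in edges            # 9 vs 8: ratio 1.125 < 1.2, distance 3 < 5
        assert (8, 9) not in edges        # 6 vs 5: ratio exactly 1.2, not < 1.2

    def test_less_equal_comparator_admits_distance_k(self, fig1_series):
        cfg = SimilarityGraphConfig(k=5, distance_comparator="less_equal")
        edges = build_similarity_graph(fig1_series, cfg).edges
        # (1, 6) is 9 vs 8 at distance exactly 5
        assert (1, 6) in edges
        assert len(edges) == 15

    def test_batch_interface(self, fig1_series):
        gm = metrics_for_ks(fig1_series, [5])[5]
        assert (gm.edges_total, gm.components, gm.bridges) == (13, 3, 2)


class TestStructuralCases:
    def test_constant_series_is_a_path_graph(self):
        graph = build_similarity_graph([4.0] * 12, SimilarityGraphConfig(k=2))
        assert graph.edges == {(i, i + 1) for i in range(1, 12)}
        gm = graph_metrics(graph)
        assert gm.components == 1
        assert gm.bridges == 11
        assert gm.triangles == 0
        assert gm.missing_direct == 0
        assert gm.isolated == 0
        assert gm.mean_edges == pytest.approx(2 * 11 / 12)

    def test_edgeless_graph(self):
        x = 10.0 ** np.arange(8)  # every ratio >= 10
        gm = graph_metrics(build_similarity_graph(x, SimilarityGraphConfig(k=5)))
        assert gm.edges_total == 0
        assert gm.components == 8
        assert gm.isolated == 8
        assert gm.missing_direct == 7
        assert gm.bridges == 0
        assert gm.triangles == 0

    def test_zero_pair_rules(self):
        x = [0.0, 0.0, 5.0, 0.0]
        both = build_similarity_graph(
            x, SimilarityGraphConfig(k=4, zero_pair_rule="both_zero_similar")
        ).edges
        assert both == {(1, 2), (1, 4), (2, 4)}
        none = build_similarity_graph(
            x, SimilarityGraphConfig(k=4, zero_pair_rule="any_zero_dissimilar")
        ).edges
        assert none == set()

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            build_similarity_graph([1.0], SimilarityGraphConfig(k=2))

    def test_negative_values_rejected(self):
        with pytest.raises(ValueError, match="non-negative"):
            build_similarity_graph([1.0, -1.0], SimilarityGraphConfig(k=2))


class TestOracles:
    @pytest.mark.parametrize("comparator", ["strict_less", "less_equal"])
    @pytest.mark.parametrize("zero_rule", ["both_zero_similar", "any_zero_dissimilar"])
    def test_edges_match_brute_force(self, rng, comparator, zero_rule):
        for _ in range(8):
            n = int(rng.integers(5, 120))
            k = int(rng.integers(2, 12))
            cfg = SimilarityGraphConfig(
                k=k, distance_comparator=comparator, zero_pair_rule=zero_rule
            )
            x = random_series(rng, n)
            assert build_similarity_graph(x, cfg).edges == brute_force_edges(x, cfg)

    def test_metrics_match_networkx(self, rng):
        for _ in range(25):
            n = int(rng.integers(5, 150))
            cfg = SimilarityGraphConfig(k=int(rng.integers(2, 15)))
            graph = build_similarity_graph(random_series(rng, n), cfg)
            gm = graph_metrics(graph)
            g = to_networkx(graph)
            assert gm.components == nx.number_connected_components(g)
            assert gm.bridges == len(list(nx.bridges(g)))
            assert gm.triangles == sum(nx.triangles(g).values()) // 3
            assert gm.isolated == len(list(nx.isolates(g)))

    def test_bridges_match_remove_and_recount(self, rng):
        for _ in range(5):
            graph = build_similarity_graph(
                random_series(rng, 40), SimilarityGraphConfig(k=6)
            )
            g = to_networkx(graph)
            base = nx.number_connected_components(g)
            expected = 0
            for e in list(g.edges):
                g.remove_edge(*e)
                expected += nx.number_connected_components(g) > base
                g.add_edge(*e)
            assert graph_metrics(graph).bridges == expected

    def test_triangles_match_all_triples(self, rng):
        for _ in range(5):
            x = random_series(rng, 30)
            graph = build_similarity_graph(x, SimilarityGraphConfig(k=8))
            edges = graph.edges
            expected = sum(
                1
                for a, b, c in itertools.combinations(range(1, 31), 3)
                if (a, b) in edges and (b, c) in edges and (a, c) in edges
            )
            assert graph_metrics(graph).triangles == expected


class TestInvariants:
    @given(c=st.floats(0.01, 1000.0))
    def test_scale_invariance(self, c):
        # continuous values: no pair sits exactly on the ratio threshold,
        # where scaling could legitimately flip the comparison
        x = np.random.default_rng(8).gamma(2.0, 100.0, size=60)
        cfg = SimilarityGraphConfig(k=5)
        assert (
            build_similarity_graph(c * x, cfg).edges
            == build_similarity_graph(x, cfg).edges
        )

    def test_edge_sets_nested_in_k(self, rng):
        x = random_series(rng, 150)
        prev = set()
        for k in (2, 3, 5, 10, 40):
            edges = build_similarity_graph(x, SimilarityGraphConfig(k=k)).edges
            assert prev <= edges
            prev = edges

    def test_components_nonincreasing_edges_nondecreasing_in_k(self, rng):
        for _ in range(5):
            x = random_series(rng, 150)
            ms = metrics_for_ks(x, (2, 5, 10, 40))
            edges = [ms[k].edges_total for k in (2, 5, 10, 40)]
            comps = [ms[k].components for k in (2, 5, 10, 40)]
            assert edges == sorted(edges)
            assert comps == sorted(comps, reverse=True)

    def test_missing_direct_is_k_independent(self, rng):
        x = random_series(rng, 200)
        ms = metrics_for_ks(x, (2, 5, 40))
        assert len({m.missing_direct for m in ms.values()}) == 1

    def test_mean_edges_ceiling_at_k2(self, rng):
        x = rng.gamma(10.0, 10.0, size=300)  # gentle series, dense graph
        strict = graph_metrics(
            build_similarity_graph(x, SimilarityGraphConfig(k=2))
        ).mean_edges
        assert strict < 2.0
        loose = graph_metrics(
            build_similarity_graph(x, SimilarityGraphConfig(k=2, distance_comparator="less_equal"))
        ).mean_edges
        assert loose <= 4.0

    def test_missing_direct_plus_direct_edges_is_n_minus_1(self, rng):
        x = random_series(rng, 100)
        graph = build_similarity_graph(x, SimilarityGraphConfig(k=5))
        direct = sum(1 for u, v in graph.edges if v - u == 1)
        assert direct + graph_metrics(graph).missing_direct == 99


def test_edge_list_export(tmp_path, fig1_series):
    graph = build_similarity_graph(fig1_series, SimilarityGraphConfig(k=5))
    path = tmp_path / "edges.txt"
    graph.write_edge_list(path)
    lines = path.read_text().strip().splitlines()
    assert len(lines) == 13
    parsed = {tuple(map(int, ln.split())) for ln in lines}
    assert parsed == graph.edges
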