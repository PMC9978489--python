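"""Centralities against hand-derived values and independent oracles."""

import itertools

import networkx as nx
import numpy as np
import pytest

from cernax.models import PpiEdge
from cernax.netcent import (
    betweenness_centrality,
    bottleneck_centrality,
    build_graph,
    centrality_table,
    closeness_centrality,
    degree_centrality,
    hub_intersection,
    shortest_path_tree,
    top_k,
)

from conftest import make_graph, random_graph


def to_nx(g):
    G = nx.Graph()
    G.add_nodes_from(g.adj)
    for u, nbrs in g.adj.items():
        for v in nbrs:
            G.add_edge(u, v)
    return G


# ---------------------------------------------------------------------------
# graph construction
# ---------------------------------------------------------------------------

def test_build_graph_score_boundary():
    edges = [PpiEdge("A", "B", 900), PpiEdge("B", "C", 899), PpiEdge("C", "D", 950)]
    g = build_graph(edges)
    assert set(g.adj) == {"A", "B", "C", "D"}
    assert g.n_edges == 2
    assert "C" not in g.adj["B"]


def test_build_graph_drops_isolated_unless_whitelisted(caplog):
    edges = [PpiEdge("A", "B", 950), PpiEdge("C", "D", 100)]
    g = build_graph(edges)
    assert set(g.adj) == {"A", "B"}
    g = build_graph(edges, node_whitelist=["C", "E"])
    assert set(g.adj) == {"A", "B", "C", "E"}
    with caplog.at_level("WARNING"):
        empty = build_graph([])
    assert empty.adj == {} and any("no edges" in m for m in caplog.messages)


# ---------------------------------------------------------------------------
# hand-derived values
# ---------------------------------------------------------------------------

def test_degree_star_and_path(star_k14, path_abc):
    assert degree_centrality(star_k14)["c"] == 4
    assert degree_centrality(path_abc)["b"] == 2


def test_closeness_path(path_abc):
    c = closeness_centrality(path_abc)
    assert c["b"] == pytest.approx(2.0)
    assert c["a"] == pytest.approx(1.5)


def test_closeness_disconnected_edges():
    g = make_graph([("a", "b"), ("c", "d")])
    assert all(v == pytest.approx(1.0) for v in closeness_centrality(g).values())


def test_closeness_single_node():
    g = make_graph([], extra_nodes=["x"])
    assert closeness_centrality(g)["x"] == 0.0


def test_closeness_classic_variant(path_abc):
    c = closeness_centrality(path_abc, variant="classic")
    assert c["b"] == pytest.approx(2 / 2)
    assert c["a"] == pytest.approx(2 / 3)
    with pytest.raises(ValueError):
        closeness_centrality(path_abc, variant="bogus")


def test_betweenness_path_star_cycle(path_abc, star_k14, cycle_c4):
    assert betweenness_centrality(path_abc)["b"] == pytest.approx(1.0)
    assert betweenness_centrality(star_k14)["c"] == pytest.approx(6.0)
    bc = betweenness_centrality(cycle_c4)
    assert all(v == pytest.approx(0.5) for v in bc.values())


def test_bottleneck_star_and_path(star_k14, path_abc):
    # from each of the 4 leaf roots the center's subtree holds 4 of 5 nodes
    assert bottleneck_centrality(star_k14)["c"] == 4
    assert bottleneck_centrality(path_abc)["b"] == 2


def test_bottleneck_leaves_of_small_trees():
    """A leaf's subtree has size 1; it scores only in trees of <= 3 nodes."""
    for n in range(2, 6):
        g = make_graph([(f"v{i}", f"v{i+1}") for i in range(n - 1)])  # path tree
        bn = bottleneck_centrality(g)
        leaf = f"v{n-1}"
        if n <= 3:
            assert bn[leaf] > 0
        else:
            assert bn[leaf] == 0


# ---------------------------------------------------------------------------
# oracle suites on random graphs
# ---------------------------------------------------------------------------

def brute_closeness(g):
    G = to_nx(g)
    out = {}
    for v in g.adj:
        dist = nx.single_source_shortest_path_length(G, v)
        out[v] = sum(1.0 / d for d in dist.values() if d > 0)
    return out


def brute_betweenness_enumeration(g):
    """Explicit enumeration of all shortest paths per pair."""
    G = to_nx(g)
    score = {v: 0.0 for v in g.adj}
    nodes = sorted(g.adj)
    for s, t in itertools.combinations(nodes, 2):
        try:
            paths = list(nx.all_shortest_paths(G, s, t))
        except nx.NetworkXNoPath:
            continue
        for path in paths:
            for v in path[1:-1]:
                score[v] += 1.0 / len(paths)
    return score


def brute_bottleneck(g):
    """Independent route: networkx distances + ancestor chains."""
    G = to_nx(g)
    bn = {v: 0 for v in g.adj}
    for s in g.adj:
        dist = nx.single_source_shortest_path_length(G, s)
        # same deterministic parent rule, built from distances alone
        parent = {}
        for v in dist:
            if v == s:
                continue
            preds = [u for u in G.neighbors(v) if dist[u] == dist[v] - 1]
            parent[v] = min(preds)
        members = list(dist)
        for v in members:
            if v == s:
                continue
            # subtree of v = nodes whose ancestor chain passes through v
            size = 0
            for w in members:
                x = w
                while x != s:
                    if x == v:
                        size += 1
                        break
                    x = parent[x]
            if size > len(members) / 4:
                bn[v] += 1
    return bn


def test_centralities_match_oracles_on_200_random_graphs():
    rng = np.random.default_rng(7)
    for i in range(200):
        g = random_graph(rng, n_max=25)
        G = to_nx(g)
        deg = degree_centrality(g)
        assert deg == {v: len(set(G.neighbors(v))) for v in g.adj}
        clo = closeness_centrality(g)
        for v, want in brute_closeness(g).items():
            assert clo[v] == pytest.approx(want)
        bet = betweenness_centrality(g)
        want_bet = nx.betweenness_centrality(G, normalized=False)
        for v in g.adj:
            assert bet[v] == pytest.approx(want_bet[v], abs=1e-9)
        bot = bottleneck_centrality(g)
        assert bot == brute_bottleneck(g)


def test_betweenness_matches_explicit_path_enumeration():
    rng = np.random.default_rng(11)
    for _ in range(20):
        g = random_graph(rng, n_max=10)
        bet = betweenness_centrality(g)
        for v, want in brute_betweenness_enumeration(g).items():
            assert bet[v] == pytest.approx(want, abs=1e-9)


def test_relabeling_permutes_but_preserves_scores():
    rng = np.random.default_rng(3)
    g = random_graph(rng, n_max=15)
    mapping = {v: f"z{v}" for v in g.adj}
    h = make_graph(
        [(mapping[u], mapping[v]) for u in g.adj for v in g.adj[u] if u < v],
        extra_nodes=[mapping[v] for v in g.adj],
    )
    for fn in (degree_centrality, closeness_centrality, betweenness_centrality, bottleneck_centrality):
        a, b = fn(g), fn(h)
        assert {mapping[v]: s for v, s in a.items()} == pytest.approx(b)


def test_adding_edge_never_decreases_degree():
    g = make_graph([("a", "b"), ("b", "c")])
    before = degree_centrality(g)
    g.add_edge("a", "c")
    after = degree_centrality(g)
    assert all(after[v] >= before[v] for v in before)


# ---------------------------------------------------------------------------
# ranking and hub intersection
# ---------------------------------------------------------------------------

def test_top_k_boundary_tie_expansion():
    assert top_k({"a": 3, "b": 2, "c": 2, "d": 1}, k=2) == ["a", "b", "c"]
    assert top_k({"a": 1, "b": 2}, k=5) == ["b", "a"]
    assert top_k({"a": 3, "b": 2, "c": 1}, k=2) == ["a", "b"]
    with pytest.raises(ValueError):
        top_k({"a": 1}, k=0)


def test_hub_intersection_star(star_k14):
    result = hub_intersection(star_k14, k=1)
    assert result.hubs == ["c"]
    for metric in ("degree", "closeness", "betweenness", "bottleneck"):
        assert result.rankings[metric][0] == "c"


def test_hub_intersection_small_graph_warns(path_abc, caplog):
    with caplog.at_level("WARNING"):
        result = hub_intersection(path_abc, k=10)
    assert "b" in result.hubs
    assert any("< k" in m for m in caplog.messages)


def test_hub_intersection_edgeless_whitelist_graph():
    g = make_graph([], extra_nodes=["a", "b", "c"])
    result = hub_intersection(g, k=2)
    # all nodes tie at zero on every metric; tie expansion keeps them all
    assert result.hubs == ["a", "b", "c"]


def test_shortest_path_tree_parent_rule():
    # diamond: s-a, s-b, a-t, b-t; t's parent must be the smaller of a, b
    g = make_graph([("s", "a"), ("s", "b"), ("a", "t"), ("b", "t")])
    parent = shortest_path_tree(g, "s")
    assert parent["t"] == "a"
    assert parent["a"] == parent["b"] == "s"


def test_centrality_table_columns(path_abc):
    rows = centrality_table(path_abc)
    assert [r["node"] for r in rows] == ["a", "b", "c"]
    assert set(rows[0]) == {"node", "degree", "closeness", "betweenness", "bottleneck"}
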