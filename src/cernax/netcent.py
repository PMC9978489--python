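"""High-confidence PPI graph construction and four-centrality hub genes.

Hub genes are the intersection of the top-k node lists under degree,
closeness, betweenness and bottleneck centrality (k = 10 by default),
computed on the graph of edges at or above a combined-score threshold
(900, i.e. 0.9, by default — STRING's "highest confidence").

All four centralities are implemented here directly so their exact
definitions are part of the package contract:

degree
    neighbour count.
closeness (harmonic form)
    ``C(v) = Σ_{w≠v reachable} 1/d(v, w)``; unreachable nodes contribute
    0, which keeps the metric well-defined on the disconnected graphs
    that score thresholding produces. A classic variant
    ``(n_comp − 1)/Σ d`` restricted to v's component is available.
betweenness
    unnormalised shortest-path betweenness over unordered pairs with
    endpoints excluded (Brandes accumulation); normalisation would not
    change rankings, which is all the hub rule uses.
bottleneck
    for every root s, build the BFS shortest-path tree of s's reachable
    component (deterministic: nodes processed in sorted label order,
    parent = lexicographically smallest equal-distance predecessor);
    a node v ≠ s scores 1 from root s when its subtree holds strictly
    more than a quarter of the tree's nodes; the centrality is the sum
    over roots.
"""

from __future__ import annotations

import logging
from collections import deque
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

from .models import PpiEdge

logger = logging.getLogger(__name__)

DEFAULT_MIN_SCORE = 900
DEFAULT_TOP_K = 10


@dataclass
class PpiGraph:
    """Undirected, unweighted adjacency after score thresholding."""

    adj: dict = field(default_factory=dict)

    @property
    def nodes(self) -> list[str]:
        return sorted(self.adj)

    @property
    def n_edges(self) -> int:
        return sum(len(nbrs) for nbrs in self.adj.values()) // 2

    def add_edge(self, a: str, b: str) -> None:
        if a == b:
            raise ValueError(f"self-loop on {a}")
        self.adj.setdefault(a, set()).add(b)
        self.adj.setdefault(b, set()).add(a)

    def add_node(self, a: str) -> None:
        self.adj.setdefault(a, set())

    def neighbors(self, a: str) -> set:
        return self.adj[a]


@dataclass(frozen=True)
class HubResult:
    """Per-metric top-k rankings and their intersection."""

    k: int
    rankings: dict  # metric name -> ranked node list (ties at k expanded)
    hubs: list[str]
    scores: dict  # metric name -> {node: score}


def build_graph(
    edges: Iterable[PpiEdge],
    min_score: int = DEFAULT_MIN_SCORE,
    node_whitelist: Optional[Iterable[str]] = None,
) -> PpiGraph:
    """Keep edges with combined_score ≥ min_score.

    Nodes left isolated by thresholding are dropped unless listed in
    ``node_whitelist`` (e.g. the full observed-target set, so that
    disconnected targets still appear in rankings).
    """
    g = PpiGraph()
    n_in = n_kept = 0
    for edge in edges:
        n_in += 1
        if edge.combined_score >= min_score:
            g.add_edge(edge.protein_a, edge.protein_b)
            n_kept += 1
    if node_whitelist is not None:
        for node in node_whitelist:
            g.add_node(node)
    if n_in == 0:
        logger.warning("build_graph received no edges")
    logger.info("build_graph: kept %d/%d edge(s) at score >= %d", n_kept, n_in, min_score)
    return g


# ---------------------------------------------------------------------------
# centralities
# ---------------------------------------------------------------------------

def degree_centrality(g: PpiGraph) -> dict[str, int]:
    return {v: len(g.adj[v]) for v in g.adj}


def _bfs_distances(g: PpiGraph, source: str) -> dict[str, int]:
    dist = {source: 0}
    queue = deque([source])
    while queue:
        u = queue.popleft()
        for w in g.adj[u]:
            if w not in dist:
                dist[w] = dist[u] + 1
                queue.append(w)
    return dist


def closeness_centrality(g: PpiGraph, variant: str = "harmonic") -> dict[str, float]:
    """Reciprocal-distance (harmonic) closeness by default; the
    ``classic`` variant is (n_comp − 1)/Σd within v's component."""
    if variant not in ("harmonic", "classic"):
        raise ValueError(f"unknown closeness variant {variant!r}")
    scores: dict[str, float] = {}
    for v in g.adj:
        dist = _bfs_distances(g, v)
        if variant == "harmonic":
            scores[v] = sum(1.0 / d for d in dist.values() if d > 0)
        else:
            total = sum(dist.values())
            scores[v] = (len(dist) - 1) / total if total > 0 else 0.0
    return scores


def betweenness_centrality(g: PpiGraph) -> dict[str, float]:
    """Brandes accumulation; unnormalised, unordered pairs, endpoints
    excluded."""
    bc = {v: 0.0 for v in g.adj}
    for s in g.adj:
        # single-source shortest-path counting
        stack: list[str] = []
        pred: dict[str, list[str]] = {v: [] for v in g.adj}
        sigma = {v: 0.0 for v in g.adj}
        sigma[s] = 1.0
        dist = {s: 0}
        queue = deque([s])
        while queue:
            u = queue.popleft()
            stack.append(u)
            for w in g.adj[u]:
                if w not in dist:
                    dist[w] = dist[u] + 1
                    queue.append(w)
                if dist[w] == dist[u] + 1:
                    sigma[w] += sigma[u]
                    pred[w].append(u)
        # back-propagation of dependencies
        delta = {v: 0.0 for v in g.adj}
        while stack:
            w = stack.pop()
            for u in pred[w]:
                delta[u] += (sigma[u] / sigma[w]) * (1.0 + delta[w])
            if w != s:
                bc[w] += delta[w]
    # each unordered pair was counted from both endpoints
    return {v: b / 2.0 for v, b in bc.items()}


def shortest_path_tree(g: PpiGraph, root: str) -> dict[str, Optional[str]]:
    """Deterministic BFS tree over root's reachable component: children
    are visited in sorted label order and each node's parent is the
    lexicographically smallest predecessor at distance − 1."""
    parent: dict[str, Optional[str]] = {root: None}
    dist = {root: 0}
    queue = deque([root])
    while queue:
        u = queue.popleft()
        for w in sorted(g.adj[u]):
            if w not in dist:
                dist[w] = dist[u] + 1
                parent[w] = u
                queue.append(w)
            elif dist[w] == dist[u] + 1 and u < parent[w]:  # type: ignore[operator]
                parent[w] = u
    return parent


def _subtree_sizes(parent: Mapping[str, Optional[str]]) -> dict[str, int]:
    children: dict = {v: [] for v in parent}
    root = None
    for v, p in parent.items():
        if p is None:
            root = v
        else:
            children[p].append(v)
    size = {v: 1 for v in parent}
    # post-order accumulation without recursion
    order: list[str] = []
    stack = [root]
    while stack:
        u = stack.pop()
        order.append(u)
        stack.extend(children[u])
    for u in reversed(order):
        for c in children[u]:
            size[u] += size[c]
    return size


def bottleneck_centrality(g: PpiGraph, fraction: float = 0.25) -> dict[str, int]:
    """Sum over roots of the indicator |subtree of v| > fraction·|tree|
    (strict), with the root never scoring in its own tree."""
    bn = {v: 0 for v in g.adj}
    for s in g.adj:
        parent = shortest_path_tree(g, s)
        size = _subtree_sizes(parent)
        n_tree = len(parent)
        for v in parent:
            if v != s and size[v] > fraction * n_tree:
                bn[v] += 1
    return bn


# ---------------------------------------------------------------------------
# ranking and hub intersection
# ---------------------------------------------------------------------------

def top_k(scores: Mapping[str, float], k: int = DEFAULT_TOP_K) -> list[str]:
    """Nodes sorted by score descending (label ascending on ties); all
    nodes tied with the k-th score are included, so the list may exceed
    k."""
    if k < 1:
        raise ValueError("k must be >= 1")
    ranked = sorted(scores, key=lambda v: (-scores[v], v))
    if len(ranked) <= k:
        return ranked
    cutoff = scores[ranked[k - 1]]
    end = k
    while end < len(ranked) and scores[ranked[end]] == cutoff:
        end += 1
    return ranked[:end]


def hub_intersection(g: PpiGraph, k: int = DEFAULT_TOP_K, closeness_variant: str = "harmonic") -> HubResult:
    """Hub genes: intersection of the four per-metric top-k lists."""
    if len(g.adj) < k:
        logger.warning(
            "hub_intersection: graph has %d node(s) < k=%d; using all nodes per metric",
            len(g.adj),
            k,
        )
    scores = {
        "degree": degree_centrality(g),
        "closeness": closeness_centrality(g, variant=closeness_variant),
        "betweenness": betweenness_centrality(g),
        "bottleneck": bottleneck_centrality(g),
    }
    rankings = {metric: top_k(s, k) for metric, s in scores.items()}
    hubs = set(g.adj)
    for ranked in rankings.values():
        hubs &= set(ranked)
    return HubResult(k=k, rankings=rankings, hubs=sorted(hubs), scores=scores)


def centrality_table(g: PpiGraph) -> "list[dict]":
    """All four scores per node, as rows ready for a TSV."""
    deg = degree_centrality(g)
    clo = closeness_centrality(g)
    bet = betweenness_centrality(g)
    bot = bottleneck_centrality(g)
    return [
        {
            "node": v,
            "degree": deg[v],
            "closeness": clo[v],
            "betweenness": bet[v],
            "bottleneck": bot[v],
        }
        for v in sorted(g.adj)
    ]
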