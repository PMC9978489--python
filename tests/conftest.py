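import numpy as np
import pytest

from cernax.models import Confidence, Direction, MirTargetEdge
from cernax.netcent import PpiGraph


def make_graph(edges, extra_nodes=()):
    g = PpiGraph()
    for a, b in edges:
        g.add_edge(a, b)
    for n in extra_nodes:
        g.add_node(n)
    return g


@pytest.fixture
def path_abc():
    """The path a - b - c."""
    return make_graph([("a", "b"), ("b", "c")])


@pytest.fixture
def star_k14():
    """Star with center c and four leaves."""
    return make_graph([("c", f"l{i}") for i in range(4)])


@pytest.fixture
def cycle_c4():
    return make_graph([("a", "b"), ("b", "c"), ("c", "d"), ("d", "a")])


def random_graph(rng, n_max=25, p=None):
    n = int(rng.integers(2, n_max + 1))
    p = float(rng.uniform(0.1, 0.6)) if p is None else p
    g = PpiGraph()
    labels = [f"n{i:02d}" for i in range(n)]
    for lab in labels:
        g.add_node(lab)
    for i in range(n):
        for j in range(i + 1, n):
            if rng.random() < p:
                g.add_edge(labels[i], labels[j])
    return g


def random_mir_edges(rng, n, mirnas, targets):
    edges = {}
    while len(edges) < n:
        mir = mirnas[rng.integers(len(mirnas))]
        tgt = targets[rng.integers(len(targets))]
        predicted = rng.random() < 0.5
        edge = MirTargetEdge(
            mir,
            tgt,
            Confidence.PREDICTED if predicted else Confidence.OBSERVED,
            float(rng.uniform(-0.8, 0.0)) if predicted else None,
            frozenset({"transcript"}),
            frozenset({"reporter_assay"}) if rng.random() < 0.5 else frozenset(),
        )
        edges[edge.key()] = edge
    return list(edges.values())


def random_calls(rng, molecules):
    return {
        m: Direction.UP if rng.random() < 0.5 else Direction.DOWN for m in molecules
    }


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
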