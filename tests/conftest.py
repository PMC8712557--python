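import networkx as nx
import numpy as np
import pytest

from netfunc import AnnotationTable, ProteinNetwork


@pytest.fixture
def triangle():
    return ProteinNetwork.from_edges([("a", "b"), ("a", "c"), ("b", "c")])


@pytest.fixture
def path3():
    """Path a - b - c."""
    return ProteinNetwork.from_edges([("a", "b"), ("b", "c")])


@pytest.fixture
def star():
    """Star with hub a and leaves b, c, d."""
    return ProteinNetwork.from_edges([("a", "b"), ("a", "c"), ("a", "d")])


def random_network(n: int, p: float, seed: int, weighted: bool = False) -> ProteinNetwork:
    """Erdős–Rényi test graph over nodes n00, n01, ..."""
    rng = np.random.default_rng(seed)
    names = [f"n{i:02d}" for i in range(n)]
    edges = []
    for i in range(n):
        for j in range(i + 1, n):
            if rng.random() < p:
                w = float(rng.uniform(0.1, 2.0)) if weighted else 1.0
                edges.append((names[i], names[j], w))
    return ProteinNetwork.from_edges(edges, nodes=names)


def random_connected_network(n: int, p: float, seed: int, weighted: bool = False) -> ProteinNetwork:
    """Random graph forced connected by threading a random spanning path."""
    net = random_network(n, p, seed, weighted=weighted)
    rng = np.random.default_rng(seed + 7)
    names = list(net.nodes)
    order = rng.permutation(len(names))
    g = net.graph
    for a, b in zip(order[:-1], order[1:]):
        u, v = names[a], names[b]
        if not g.has_edge(u, v):
            w = float(rng.uniform(0.1, 2.0)) if weighted else 1.0
            g.add_edge(u, v, weight=w)
    assert nx.is_connected(g)
    return ProteinNetwork(g)


@pytest.fixture
def handvote_paths(tmp_path):
    """Six-protein weighted network with worked-by-hand voting outcomes."""
    edges = tmp_path / "edges.tsv"
    edges.write_text(
        "p1\tp2\t2\np1\tp3\t1\np2\tp3\t1\np3\tp4\t1\np4\tp5\t2\np4\tp6\t1\np5\tp6\t1\n"
    )
    ann = tmp_path / "annotations.tsv"
    ann.write_text("p1\tA\np2\tA\np3\tA;B\np4\tB\np5\tB\np6\tA\n")
    return edges, ann


def annotate_all(net: ProteinNetwork, label: str = "F1", labels=None) -> AnnotationTable:
    universe = labels or (label,)
    return AnnotationTable({u: {label} for u in net.nodes}, labels=universe)
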