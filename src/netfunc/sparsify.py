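"""Connectivity-preserving random sparsification.

A sparse subnetwork is built in two steps: a random minimum spanning tree
(independent uniform edge weights drawn from a seeded generator guarantee a
uniformly random tree among MSTs and preserve connectivity), then expansion
with a seeded random sample of the remaining original edges until the target
edge count — round-half-up of fraction × |E|, floored at |V| − 1 so the
result stays connected.
"""

from __future__ import annotations

import logging
import math

import networkx as nx
import numpy as np

from .model import ProteinNetwork, ValidationError

logger = logging.getLogger("netfunc")


def _largest_component(net: ProteinNetwork) -> tuple[nx.Graph, bool]:
    g = net.graph
    if g.number_of_nodes() == 0:
        raise ValidationError("empty network")
    if nx.is_connected(g):
        return g, True
    comp = max(nx.connected_components(g), key=lambda c: (len(c), sorted(c)[0]))
    logger.warning(
        "sparsify: disconnected input; using the largest component (%d of %d nodes)",
        len(comp), g.number_of_nodes(),
    )
    return g.subgraph(comp).copy(), False


def random_mst(net: ProteinNetwork, seed: int) -> set[tuple[str, str]]:
    """Random spanning tree edges of the (largest component of the) network.

    Every edge receives an independent uniform(0, 1) weight from the seeded
    generator; the MST of those weights is returned as canonical (min, max)
    node pairs, |V| − 1 of them.
    """
    g, _ = _largest_component(net)
    rng = np.random.default_rng(seed)
    h = nx.Graph()
    h.add_nodes_from(g.nodes)
    for u, v, _w in sorted((min(a, b), max(a, b), d["weight"]) for a, b, d in g.edges(data=True)):
        h.add_edge(u, v, rand=rng.random())
    mst = nx.minimum_spanning_edges(h, weight="rand", data=False)
    return {(min(u, v), max(u, v)) for u, v in mst}


def sparsify(net: ProteinNetwork, fraction: float, seed: int) -> ProteinNetwork:
    """Connected subnetwork with max(round(fraction·|E|), |V|−1) original edges.

    Original weights are retained and the node set is unchanged.  When the
    fraction target falls below the spanning-tree size, connectivity wins and
    a warning is logged.
    """
    if not (0.0 < fraction <= 1.0):
        raise ValidationError("fraction must lie in (0, 1]")
    g, _connected = _largest_component(net)
    n_comp_nodes = g.number_of_nodes()
    n_edges = g.number_of_edges()
    target = int(math.floor(fraction * n_edges + 0.5))
    floor = n_comp_nodes - 1
    if target < floor:
        logger.warning(
            "sparsify: fraction %.3g targets %d edges but the spanning tree needs %d; using %d",
            fraction, target, floor, floor,
        )
        target = floor
    mst_edges = random_mst(ProteinNetwork(g.copy()), seed)
    non_mst = sorted(
        (min(u, v), max(u, v)) for u, v in g.edges() if (min(u, v), max(u, v)) not in mst_edges
    )
    n_extra = target - len(mst_edges)
    rng = np.random.default_rng(seed + 1)
    extra_idx = rng.choice(len(non_mst), size=min(n_extra, len(non_mst)), replace=False)
    chosen = mst_edges | {non_mst[i] for i in extra_idx.tolist()}
    return ProteinNetwork.from_edges(
        ((u, v, g[u][v]["weight"]) for u, v in chosen), nodes=net.nodes
    )
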