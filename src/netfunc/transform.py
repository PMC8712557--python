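"""Network reconstruction and edge enrichment.

Reconstruction discards every original interaction and rebuilds the edge set
from a similarity matrix, either per node (top-k highest-scoring partners,
the default) or globally (a score threshold chosen so the surviving pair
count is as close as possible to the original edge count).  Enrichment keeps
the original network untouched and adds, per node, up to k similarity-inferred
neighbors that are not already explicit neighbors.

All transforms are deterministic functions of (network, similarity, k):
ties are broken by ascending node id and zero-score partners are never
materialized as edges.
"""

from __future__ import annotations

import logging

from .model import EnrichedNetwork, ProteinNetwork, SimilarityMatrix, ValidationError

logger = logging.getLogger("netfunc")


def top_k_neighbors(
    S: SimilarityMatrix,
    node: str,
    k: int,
    exclude: frozenset[str] | set[str] = frozenset(),
) -> list[tuple[str, float]]:
    """Up to k strictly-positive-score partners of ``node``, best first.

    Sorted by descending score, ties by ascending node id; ``exclude`` members
    and the node itself are never returned.
    """
    row = S.row(node)
    candidates = [
        (other, float(row[i]))
        for i, other in enumerate(S.index)
        if row[i] > 0 and other != node and other not in exclude
    ]
    candidates.sort(key=lambda rec: (-rec[1], rec[0]))
    return candidates[:k]


def _check_index(net: ProteinNetwork, S: SimilarityMatrix) -> None:
    missing = [u for u in net.nodes if not S.has_node(u)]
    if missing:
        raise ValidationError(f"similarity matrix lacks {len(missing)} network node(s), e.g. {missing[0]!r}")


def reconstruct_topk(net: ProteinNetwork, S: SimilarityMatrix, k: int) -> ProteinNetwork:
    """Replace all edges by each node's top-k positive-score partners.

    Per-node directional selections are symmetrized by union (an edge exists
    if either endpoint selected it) with the similarity score as weight.
    The node set is unchanged; nodes without positive scores become isolated.
    """
    _check_index(net, S)
    edges: dict[tuple[str, str], float] = {}
    for u in net.nodes:
        for v, score in top_k_neighbors(S, u, k):
            if net.has_node(v):
                edges[(min(u, v), max(u, v))] = score
    return ProteinNetwork.from_edges(
        ((u, v, w) for (u, v), w in edges.items()), nodes=net.nodes
    )


def reconstruct_threshold(net: ProteinNetwork, S: SimilarityMatrix) -> ProteinNetwork:
    """Replace all edges by the pairs scoring strictly above a chosen threshold.

    The threshold is the one whose strictly-above count is closest to the
    original edge count; ties prefer the smaller threshold (more edges).  The
    result may strand nodes.
    """
    _check_index(net, S)
    nodes = net.nodes
    pos = [S.position(u) for u in nodes]
    pairs: list[tuple[float, str, str]] = []
    for a in range(len(nodes)):
        for b in range(a + 1, len(nodes)):
            s = float(S.scores[pos[a], pos[b]])
            if s > 0:
                pairs.append((s, nodes[a], nodes[b]))
    if not pairs:
        logger.warning("reconstruct_threshold: all-zero similarity matrix; returning empty network")
        return ProteinNetwork.from_edges((), nodes=nodes)
    pairs.sort(key=lambda rec: (-rec[0], rec[1], rec[2]))
    target = net.n_edges
    # candidate counts: after each run of equal scores, plus zero
    scores = [rec[0] for rec in pairs]
    counts = [0]
    for i in range(1, len(scores)):
        if scores[i] != scores[i - 1]:
            counts.append(i)
    counts.append(len(scores))
    # closest count to target; ties -> larger count (smaller threshold)
    best = min(counts, key=lambda c: (abs(c - target), -c))
    if best < target:
        logger.warning(
            "reconstruct_threshold: only %d positive pair(s) available for a target of %d edges",
            best if best else len(scores), target,
        )
    kept = pairs[:best]
    return ProteinNetwork.from_edges(((u, v, s) for s, u, v in kept), nodes=nodes)


def enrich(
    net: ProteinNetwork,
    S: SimilarityMatrix,
    k: int,
    allow_overlap: bool = False,
) -> EnrichedNetwork:
    """Keep the original network and add per-node top-k inferred neighbors.

    Inferred candidates exclude each node's explicit neighborhood (enrichment
    adds information the original network lacks); ``allow_overlap`` restores
    double-counting for sensitivity analysis.
    """
    _check_index(net, S)
    inferred: dict[str, list[tuple[str, float]]] = {}
    node_set = set(net.nodes)
    for u in net.nodes:
        exclude = set() if allow_overlap else net.neighbor_set(u)
        recs = [
            (v, s) for v, s in top_k_neighbors(S, u, k, exclude=exclude) if v in node_set
        ]
        if recs:
            inferred[u] = recs
    return EnrichedNetwork(explicit=net, inferred=inferred, allow_overlap=allow_overlap)
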