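"""Function prediction: weighted-voting (majority) and Gibbs-sampling
collective classification.

A query protein's label distribution is a weighted vote of its neighbors:
each neighbor casts its edge weight (explicit layer) or similarity score
(inferred layer) for every function it carries, and each layer is normalized
to a probability vector.  On an enriched network the two layers are mixed
with weight λ on the explicit votes and 1 − λ on the inferred ones.

The majority method is one shot: only annotated neighbors vote.  The Gibbs
sampler is collective: every unannotated protein holds one currently-sampled
label; in each iteration (seeded random order) a protein recomputes its
distribution — annotated neighbors contribute all their true labels,
unannotated neighbors their single sampled label — and resamples.  After a
burn-in period, each sampling iteration records the ranked label order of
the current distribution; the final ranking takes, at each rank, the modal
label of that rank's column, never repeating a label.
"""

from __future__ import annotations

import logging
from collections.abc import Mapping
from dataclasses import dataclass, field

import numpy as np

from .model import (
    AnnotationTable,
    EnrichedNetwork,
    ExperimentConfig,
    ProteinNetwork,
    ValidationError,
)

logger = logging.getLogger("netfunc")

Network = ProteinNetwork | EnrichedNetwork


@dataclass
class FunctionDistribution:
    """Per-label probability vector a⃗_x; ``uninformative`` marks no-evidence queries."""

    probs: np.ndarray
    uninformative: bool = False


@dataclass(frozen=True)
class RankedPrediction:
    """Ordered distinct labels for one query, best first."""

    labels: tuple[str, ...]
    uninformative: bool = False


# ---------------------------------------------------------------------------
# voting
# ---------------------------------------------------------------------------


def _layer_votes(
    contributions: list[tuple[float, tuple[int, ...]]],
    m: int,
    normalize_multilabel: bool,
) -> np.ndarray | None:
    """Normalized vote vector of one layer; None when no evidence exists."""
    votes = np.zeros(m)
    for weight, label_idx in contributions:
        if not label_idx:
            continue
        w = weight / len(label_idx) if normalize_multilabel else weight
        for j in label_idx:
            votes[j] += w
    total = votes.sum()
    if total <= 0:
        return None
    return votes / total


def _mix_layers(
    explicit: np.ndarray | None,
    inferred: np.ndarray | None,
    lam: float,
    m: int,
) -> FunctionDistribution:
    if explicit is not None and inferred is not None:
        return FunctionDistribution(lam * explicit + (1.0 - lam) * inferred)
    if explicit is not None:
        return FunctionDistribution(explicit)
    if inferred is not None:
        return FunctionDistribution(inferred)
    return FunctionDistribution(np.full(m, 1.0 / m) if m else np.zeros(0), uninformative=True)


def vote_distribution(
    query: str,
    explicit_neighbors: list[tuple[str, float]],
    inferred_neighbors: list[tuple[str, float]],
    annotations: AnnotationTable,
    lam: float = 0.7,
    normalize_multilabel: bool = False,
) -> FunctionDistribution:
    """Weighted-vote distribution of a query from its two neighbor layers.

    Only annotated neighbors contribute (each casts its full weight per label
    it carries, unless ``normalize_multilabel``); each layer is normalized to
    sum to 1, and both-present layers are mixed as λ·explicit + (1−λ)·inferred.
    With a single informative layer the pure per-layer vote is returned; with
    none, a uniform distribution flagged uninformative.
    """
    if not (0.0 <= lam <= 1.0):
        raise ValidationError("lambda must lie in [0, 1]")
    m = annotations.m

    def prep(neighbors):
        out = []
        for node, weight in neighbors:
            if node == query or not annotations.is_annotated(node):
                continue
            out.append((weight, annotations.label_indices(node)))
        return out

    explicit = _layer_votes(prep(explicit_neighbors), m, normalize_multilabel)
    inferred = _layer_votes(prep(inferred_neighbors), m, normalize_multilabel)
    return _mix_layers(explicit, inferred, lam, m)


def rank_labels(
    dist: FunctionDistribution,
    labels: tuple[str, ...],
    R: int,
    rng: np.random.Generator | None = None,
) -> tuple[str, ...]:
    """Labels sorted by descending probability, truncated to R.

    Ties break by ascending label index (deterministic mode) or by a seeded
    shuffle among tied labels when ``rng`` is given.
    """
    if R < 1:
        raise ValidationError("R must be >= 1")
    probs = dist.probs
    m = len(labels)
    if rng is None:
        tie_key = np.arange(m)
    else:
        tie_key = rng.permutation(m)
    order = np.lexsort((tie_key, -probs))
    return tuple(labels[i] for i in order[: min(R, m)])


# ---------------------------------------------------------------------------
# majority method
# ---------------------------------------------------------------------------


def _split_layers(network: Network, query: str) -> tuple[list[tuple[str, float]], list[tuple[str, float]]]:
    if isinstance(network, EnrichedNetwork):
        return network.explicit_neighbors(query), network.inferred_neighbors(query)
    return network.neighbors(query), []


def majority_predict(
    network: Network,
    annotations: AnnotationTable,
    query: str,
    cfg: ExperimentConfig | None = None,
) -> RankedPrediction:
    """One-shot weighted vote of the query's annotated neighbors."""
    cfg = cfg or ExperimentConfig()
    explicit, inferred = _split_layers(network, query)
    dist = vote_distribution(
        query, explicit, inferred, annotations,
        lam=cfg.lam, normalize_multilabel=cfg.normalize_multilabel,
    )
    R = cfg.n_ranks if cfg.n_ranks is not None else annotations.m
    ranked = rank_labels(dist, annotations.labels, R) if annotations.m else ()
    return RankedPrediction(labels=ranked, uninformative=dist.uninformative)


# ---------------------------------------------------------------------------
# Gibbs-sampling collective classification
# ---------------------------------------------------------------------------


@dataclass
class GibbsResult(Mapping):
    """Mapping query → RankedPrediction, plus the raw sampler record.

    ``samples[x]`` is the s × m matrix M_x of per-iteration ranked label
    indices; ``sampled_counts[x]`` counts how many times each label was the
    protein's sampled state during the sampling period.
    """

    predictions: dict[str, RankedPrediction]
    samples: dict[str, np.ndarray] = field(default_factory=dict)
    sampled_counts: dict[str, np.ndarray] = field(default_factory=dict)

    def __getitem__(self, key):
        return self.predictions[key]

    def __iter__(self):
        return iter(self.predictions)

    def __len__(self):
        return len(self.predictions)


def _reachable_from_annotated(
    network: Network, annotated: set[str]
) -> set[str]:
    """Nodes connected (over both layers) to at least one annotated protein."""
    adj: dict[str, set[str]] = {}
    if isinstance(network, EnrichedNetwork):
        nodes = network.nodes
        for u in nodes:
            adj.setdefault(u, set())
            for v, _ in network.explicit_neighbors(u):
                adj[u].add(v)
            for v, _ in network.inferred_neighbors(u):
                adj[u].add(v)
                adj.setdefault(v, set()).add(u)
    else:
        nodes = network.nodes
        for u in nodes:
            adj[u] = network.neighbor_set(u)
    seen = set(a for a in annotated if a in adj)
    frontier = list(seen)
    while frontier:
        u = frontier.pop()
        for v in adj.get(u, ()):
            if v not in seen:
                seen.add(v)
                frontier.append(v)
    return seen


def _aggregate_ranks(samples: np.ndarray, m: int, R: int, labels: tuple[str, ...]) -> tuple[str, ...]:
    """Per-column modal label with distinct-label enforcement across ranks.

    Ties break by earlier first occurrence in the column, then label index.
    """
    s = samples.shape[0]
    placed: list[int] = []
    placed_set: set[int] = set()
    for j in range(min(R, m)):
        column = samples[:, j]
        freq = np.bincount(column, minlength=m)
        first_occ = np.full(m, s)
        for i in range(s - 1, -1, -1):
            first_occ[column[i]] = i
        best = min(
            (lab for lab in range(m) if lab not in placed_set),
            key=lambda lab: (-freq[lab], first_occ[lab], lab),
        )
        placed.append(best)
        placed_set.add(best)
    return tuple(labels[j] for j in placed)


def gibbs_classify(
    network: Network,
    annotations: AnnotationTable,
    cfg: ExperimentConfig | None = None,
) -> GibbsResult:
    """Collective classification of all unannotated proteins in the network.

    Bootstrapping estimates each unannotated protein's distribution from its
    annotated neighbors only and samples an initial label.  During burn-in
    and sampling, proteins are updated in a freshly shuffled order per
    iteration; unannotated neighbors contribute their current sampled label.
    Sampling iterations record the ranked label order into M_x; the final
    prediction is the per-rank modal label of M_x.
    """
    cfg = cfg or ExperimentConfig()
    m = annotations.m
    labels = annotations.labels
    nodes = network.nodes
    annotated = {u for u in nodes if annotations.is_annotated(u)}
    if not annotated:
        raise ValidationError("gibbs_classify requires at least one annotated protein")
    unannotated = sorted(set(nodes) - annotated)
    R = cfg.n_ranks if cfg.n_ranks is not None else m

    if not unannotated:
        return GibbsResult(predictions={})

    reachable = _reachable_from_annotated(network, annotated)
    rng = np.random.default_rng(cfg.seed)

    # precomputed neighbor structure: (node, weight, true_label_indices or None)
    unann_set = set(unannotated)
    neighbor_info: dict[str, tuple[list, list]] = {}
    for x in unannotated:
        explicit, inferred = _split_layers(network, x)

        def pack(neighbors, x=x):
            packed = []
            for v, w in neighbors:
                if v == x:
                    continue
                if v in annotated:
                    packed.append((v, w, annotations.label_indices(v)))
                elif v in unann_set:
                    packed.append((v, w, None))
            return packed

        neighbor_info[x] = (pack(explicit), pack(inferred))

    def current_distribution(x: str, current: dict[str, int]) -> FunctionDistribution:
        exp_packed, inf_packed = neighbor_info[x]
        def contrib(packed):
            out = []
            for v, w, labs in packed:
                if labs is None:
                    out.append((w, (current[v],)))
                else:
                    out.append((w, labs))
            return out
        explicit = _layer_votes(contrib(exp_packed), m, cfg.normalize_multilabel)
        inferred = _layer_votes(contrib(inf_packed), m, cfg.normalize_multilabel)
        return _mix_layers(explicit, inferred, cfg.lam, m)

    # --- bootstrapping: annotated neighbors only --------------------------
    current: dict[str, int] = {}
    for x in unannotated:
        explicit, inferred = _split_layers(network, x)
        dist = vote_distribution(
            x, explicit, inferred, annotations,
            lam=cfg.lam, normalize_multilabel=cfg.normalize_multilabel,
        )
        current[x] = int(rng.choice(m, p=dist.probs)) if not dist.uninformative else int(rng.integers(m))

    # --- burn-in + sampling ----------------------------------------------
    s = cfg.n_samples
    samples = {x: np.empty((s, m), dtype=np.int64) for x in unannotated}
    counts = {x: np.zeros(m, dtype=np.int64) for x in unannotated}
    det_tie = np.arange(m)
    for it in range(cfg.burn_in + s):
        order = rng.permutation(len(unannotated))
        for idx in order:
            x = unannotated[idx]
            dist = current_distribution(x, current)
            current[x] = int(rng.choice(m, p=dist.probs))
            if it >= cfg.burn_in:
                rank_order = np.lexsort((det_tie, -dist.probs))
                samples[x][it - cfg.burn_in] = rank_order
                counts[x][current[x]] += 1

    predictions = {}
    for x in unannotated:
        ranked = _aggregate_ranks(samples[x], m, R, labels)
        predictions[x] = RankedPrediction(labels=ranked, uninformative=x not in reachable)
    return GibbsResult(predictions=predictions, samples=samples, sampled_counts=counts)
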