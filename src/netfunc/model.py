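"""Domain types shared by all stages.

The package works with four kinds of objects:

* :class:`ProteinNetwork` — an undirected graph of proteins whose edge
  weights are interaction confidences (1.0 everywhere for unweighted input).
* :class:`AnnotationTable` — a partial multi-label map from proteins to a
  fixed, ordered universe of function labels.
* :class:`SimilarityMatrix` — a square, symmetric, zero-diagonal matrix of
  pairwise protein similarity scores (sequence scores loaded from disk, or
  topological indices computed by :mod:`netfunc.similarity`).
* :class:`EnrichedNetwork` — a two-layer view of a network: the unchanged
  explicit interactions plus per-node similarity-inferred neighbor lists.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np

logger = logging.getLogger("netfunc")


class ValidationError(ValueError):
    """Raised when an input violates a domain invariant."""


class ParseError(ValueError):
    """Raised when a file cannot be parsed; message names the line number."""


# ---------------------------------------------------------------------------
# ProteinNetwork
# ---------------------------------------------------------------------------


class ProteinNetwork:
    """Undirected protein interaction network with positive confidence weights.

    Invariants enforced at construction: no self-loops, strictly positive
    weights, (u, v) and (v, u) are the same record.  Isolated nodes are
    permitted and retained.
    """

    __slots__ = ("_g",)

    def __init__(self, graph: nx.Graph | None = None):
        g = nx.Graph() if graph is None else graph
        for u, v, data in g.edges(data=True):
            if u == v:
                raise ValidationError(f"self-loop on node {u!r}")
            w = float(data.get("weight", 1.0))
            if not (w > 0):
                raise ValidationError(f"non-positive weight {w} on edge ({u!r}, {v!r})")
            data["weight"] = w
        self._g = g

    @classmethod
    def from_edges(
        cls,
        edges: Iterable[tuple[str, str] | tuple[str, str, float]],
        nodes: Iterable[str] = (),
    ) -> "ProteinNetwork":
        """Build a network from (u, v[, w]) tuples; duplicates keep max weight."""
        g = nx.Graph()
        g.add_nodes_from(nodes)
        for edge in edges:
            u, v = edge[0], edge[1]
            w = float(edge[2]) if len(edge) > 2 else 1.0
            if g.has_edge(u, v):
                w = max(w, g[u][v]["weight"])
            g.add_edge(u, v, weight=w)
        return cls(g)

    # -- introspection ------------------------------------------------------

    @property
    def graph(self) -> nx.Graph:
        return self._g

    @property
    def nodes(self) -> tuple[str, ...]:
        return tuple(sorted(self._g.nodes))

    @property
    def n_nodes(self) -> int:
        return self._g.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self._g.number_of_edges()

    def has_node(self, u: str) -> bool:
        return self._g.has_node(u)

    def has_edge(self, u: str, v: str) -> bool:
        return self._g.has_edge(u, v)

    def weight(self, u: str, v: str) -> float:
        return self._g[u][v]["weight"]

    def degree(self, u: str) -> int:
        return self._g.degree(u)

    def neighbors(self, u: str) -> list[tuple[str, float]]:
        """Sorted (neighbor, weight) pairs of the open neighborhood of ``u``."""
        if not self._g.has_node(u):
            raise ValidationError(f"unknown node {u!r}")
        return sorted((v, d["weight"]) for v, d in self._g[u].items())

    def neighbor_set(self, u: str) -> set[str]:
        if not self._g.has_node(u):
            raise ValidationError(f"unknown node {u!r}")
        return set(self._g[u])

    def edges(self) -> list[tuple[str, str, float]]:
        """Canonical edge list: (min, max, weight), sorted."""
        return sorted(
            (min(u, v), max(u, v), d["weight"]) for u, v, d in self._g.edges(data=True)
        )

    def mean_degree(self) -> float:
        n = self.n_nodes
        return 2.0 * self.n_edges / n if n else 0.0

    def copy(self) -> "ProteinNetwork":
        return ProteinNetwork(self._g.copy())

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ProteinNetwork):
            return NotImplemented
        return set(self._g.nodes) == set(other._g.nodes) and self.edges() == other.edges()

    def __hash__(self):  # pragma: no cover - mutable container
        raise TypeError("ProteinNetwork is not hashable")

    def __repr__(self) -> str:
        return f"ProteinNetwork(n_nodes={self.n_nodes}, n_edges={self.n_edges})"


# ---------------------------------------------------------------------------
# AnnotationTable
# ---------------------------------------------------------------------------


class AnnotationTable:
    """Partial multi-label protein → function-label assignment.

    ``labels`` is the ordered universe of the m function identifiers;
    ``assignments`` maps each *annotated* protein to a non-empty subset of it.
    The indicator f_{i,j} (1 iff protein i carries label j) is derived on
    demand by :meth:`indicator`.
    """

    __slots__ = ("labels", "assignments", "_label_pos")

    def __init__(
        self,
        assignments: Mapping[str, Iterable[str]],
        labels: Sequence[str] | None = None,
    ):
        assign: dict[str, frozenset[str]] = {}
        for protein, labs in assignments.items():
            labs = frozenset(labs)
            if not labs:
                raise ValidationError(f"protein {protein!r} has an empty label set")
            assign[protein] = labs
        if labels is None:
            universe: tuple[str, ...] = tuple(sorted(set().union(*assign.values()))) if assign else ()
        else:
            universe = tuple(labels)
            if len(set(universe)) != len(universe):
                raise ValidationError("duplicate labels in universe")
            known = set(universe)
            for protein, labs in assign.items():
                unknown = labs - known
                if unknown:
                    raise ValidationError(
                        f"protein {protein!r} carries labels outside the universe: {sorted(unknown)}"
                    )
        self.labels = universe
        self.assignments = assign
        self._label_pos = {lab: j for j, lab in enumerate(universe)}

    # -- introspection ------------------------------------------------------

    @property
    def m(self) -> int:
        return len(self.labels)

    @property
    def proteins(self) -> tuple[str, ...]:
        return tuple(sorted(self.assignments))

    def is_annotated(self, protein: str) -> bool:
        return protein in self.assignments

    def label_index(self, label: str) -> int:
        return self._label_pos[label]

    def label_indices(self, protein: str) -> tuple[int, ...]:
        """Sorted positions of the labels carried by ``protein``."""
        return tuple(sorted(self._label_pos[lab] for lab in self.assignments[protein]))

    def indicator(self, protein: str) -> np.ndarray:
        """f_{i,·}: binary vector of length m; zeros for unannotated proteins."""
        vec = np.zeros(self.m)
        if protein in self.assignments:
            vec[list(self.label_indices(protein))] = 1.0
        return vec

    def mean_labels_per_protein(self) -> float:
        if not self.assignments:
            raise ValidationError("no annotated proteins")
        return sum(len(v) for v in self.assignments.values()) / len(self.assignments)

    # -- derived tables -----------------------------------------------------

    def without(self, protein: str) -> "AnnotationTable":
        """Same universe, with ``protein`` hidden (for leave-one-out)."""
        assign = {p: labs for p, labs in self.assignments.items() if p != protein}
        return AnnotationTable(assign, labels=self.labels)

    def restrict(self, proteins: Iterable[str]) -> "AnnotationTable":
        """Same universe, keeping only the given proteins' annotations."""
        keep = set(proteins)
        assign = {p: labs for p, labs in self.assignments.items() if p in keep}
        return AnnotationTable(assign, labels=self.labels)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, AnnotationTable):
            return NotImplemented
        return self.labels == other.labels and self.assignments == other.assignments

    def __repr__(self) -> str:
        return f"AnnotationTable(m={self.m}, n_annotated={len(self.assignments)})"


# ---------------------------------------------------------------------------
# SimilarityMatrix
# ---------------------------------------------------------------------------


class SimilarityMatrix:
    """Square symmetric non-negative score matrix with a zero diagonal.

    Self-similarity is ignored by construction: S[x, x] = 0.  The node order
    of ``index`` is deterministic (callers sort), so downstream runs are
    reproducible.
    """

    __slots__ = ("index", "scores", "_pos")

    def __init__(self, index: Sequence[str], scores: np.ndarray, *, validate: bool = True):
        index = tuple(index)
        scores = np.asarray(scores, dtype=float)
        if scores.ndim != 2 or scores.shape[0] != scores.shape[1]:
            raise ValidationError(f"scores must be square, got shape {scores.shape}")
        if len(index) != scores.shape[0]:
            raise ValidationError("index length does not match matrix size")
        if validate:
            if np.any(scores < 0):
                raise ValidationError("negative similarity score")
            if not np.allclose(scores, scores.T, rtol=1e-9, atol=1e-12):
                raise ValidationError("similarity matrix is not symmetric")
            if np.any(np.diag(scores) != 0):
                scores = scores.copy()
                np.fill_diagonal(scores, 0.0)
        self.index = index
        self.scores = scores
        self._pos = {node: i for i, node in enumerate(index)}

    @property
    def n(self) -> int:
        return len(self.index)

    def has_node(self, u: str) -> bool:
        return u in self._pos

    def position(self, u: str) -> int:
        try:
            return self._pos[u]
        except KeyError:
            raise ValidationError(f"unknown node {u!r}") from None

    def score(self, u: str, v: str) -> float:
        return float(self.scores[self.position(u), self.position(v)])

    def row(self, u: str) -> np.ndarray:
        return self.scores[self.position(u)]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, SimilarityMatrix):
            return NotImplemented
        return self.index == other.index and np.allclose(
            self.scores, other.scores, rtol=1e-12, atol=1e-12
        )

    def __repr__(self) -> str:
        return f"SimilarityMatrix(n={self.n})"


# ---------------------------------------------------------------------------
# EnrichedNetwork
# ---------------------------------------------------------------------------


@dataclass
class EnrichedNetwork:
    """Two-layer network: unchanged explicit edges plus inferred neighbor lists.

    ``inferred`` maps a node to up to k (neighbor, score) records; a pair never
    appears in both layers and every inferred score is strictly positive.
    """

    explicit: ProteinNetwork
    inferred: dict[str, list[tuple[str, float]]]
    allow_overlap: bool = False

    def __post_init__(self):
        for node, recs in self.inferred.items():
            if not self.explicit.has_node(node):
                raise ValidationError(f"inferred layer names unknown node {node!r}")
            nbrs = self.explicit.neighbor_set(node)
            for other, score in recs:
                if other == node:
                    raise ValidationError(f"inferred self-pair on {node!r}")
                if not (score > 0):
                    raise ValidationError(
                        f"non-positive inferred score {score} for ({node!r}, {other!r})"
                    )
                if other in nbrs and not self.allow_overlap:
                    raise ValidationError(
                        f"pair ({node!r}, {other!r}) appears in both layers"
                    )

    @property
    def nodes(self) -> tuple[str, ...]:
        return self.explicit.nodes

    def explicit_neighbors(self, u: str) -> list[tuple[str, float]]:
        return self.explicit.neighbors(u)

    def inferred_neighbors(self, u: str) -> list[tuple[str, float]]:
        return list(self.inferred.get(u, ()))


# ---------------------------------------------------------------------------
# ExperimentConfig
# ---------------------------------------------------------------------------

#: Default inferred-edge budgets per similarity index: 5 for sequence scores
#: and 30 for the topological indices (the FS/RWR settings; the remaining
#: indices share the topological default).
DEFAULT_K: dict[str, int] = {
    "sequence": 5,
    "cn": 30,
    "jaccard": 30,
    "fs": 30,
    "fsr": 30,
    "katz": 30,
    "rwr": 30,
}


@dataclass
class ExperimentConfig:
    """Tunable parameters for transforms, inference and evaluation.

    ``k`` is the per-node inferred-edge budget; ``lam`` the explicit/inferred
    mixture weight (0.7 by default); ``katz_beta`` the walk damping (None →
    0.5/ρ(A)); ``rwr_c`` the walker transmit probability; ``burn_in`` /
    ``n_samples`` the Gibbs iteration counts; ``n_ranks`` the number of ranked
    predictions R (None → derived from the annotation table).
    """

    k: int = 30
    lam: float = 0.7
    katz_beta: float | None = None
    rwr_c: float = 0.9
    rwr_tol: float = 1e-10
    burn_in: int = 50
    n_samples: int = 100
    n_ranks: int | None = None
    seed: int = 0
    annotated_fraction: float = 0.5
    n_repeats: int = 10
    fs_combine: str = "product"
    normalize_multilabel: bool = False
    allow_overlap: bool = False

    def __post_init__(self):
        if self.k < 0:
            raise ValidationError("k must be non-negative")
        if not (0.0 <= self.lam <= 1.0):
            raise ValidationError("lambda must lie in [0, 1]")
        if self.katz_beta is not None and not (self.katz_beta > 0):
            raise ValidationError("katz_beta must be positive")
        if not (0.0 < self.rwr_c < 1.0):
            raise ValidationError("rwr_c must lie in (0, 1)")
        if self.burn_in < 0 or self.n_samples < 1:
            raise ValidationError("burn_in must be >= 0 and n_samples >= 1")
        if self.n_ranks is not None and self.n_ranks < 1:
            raise ValidationError("n_ranks must be >= 1")
        if not (0.0 < self.annotated_fraction <= 1.0):
            raise ValidationError("annotated_fraction must lie in (0, 1]")
        if self.n_repeats < 1:
            raise ValidationError("n_repeats must be >= 1")
        if self.fs_combine not in ("product", "sum"):
            raise ValidationError("fs_combine must be 'product' or 'sum'")

    def with_(self, **kwargs) -> "ExperimentConfig":
        return replace(self, **kwargs)

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)
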