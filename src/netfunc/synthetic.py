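"""Synthetic annotated PPI networks with label-correlated sequence similarity.

The generator plants a multi-label community structure: every protein first
draws a label set (shifted Poisson count, minimum one label), then a
planted-partition-style graph connects pairs sharing at least one label with
probability ``p_in`` and all other pairs with probability ``p_out``.  Data
quality defects are injected afterwards: a fraction of the true edges is
deleted (incompleteness) and a fraction, relative to the true edge count, of
random non-edges is added (spurious interactions).

The "sequence" similarity matrix is drawn independently of the noisy
topology so it carries genuinely complementary label signal: a same-label
pair receives a high score with probability ``similarity_signal``, a
different-label pair with the (smaller) probability ``cross_signal`` —
sequence homology does not guarantee shared function, so cross-label hits
model homologous but functionally diverged pairs.  Scores are uniform draws
from per-class ranges.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .model import AnnotationTable, ProteinNetwork, SimilarityMatrix, ValidationError

logger = logging.getLogger("netfunc")


@dataclass
class SyntheticSpec:
    """Parameters of one synthetic dataset (network, annotations, similarity).

    Defaults emulate a mid-size, moderately noisy interaction screen: a few
    hundred proteins, six broad function categories with ~1.5 labels each,
    mean degree around six with clear homophily, 20% of true interactions
    missing and 20% spurious ones added, and a sequence-similarity matrix
    with sparse coverage: ~3% of same-function pairs score highly (detectable
    homology is the exception, not the rule) against a ~1% rate among
    functionally unrelated pairs.
    """

    n_proteins: int = 300
    m_labels: int = 6
    labels_per_protein: float = 1.5
    p_in: float = 0.05
    p_out: float = 0.005
    spurious_edge_rate: float = 0.2
    missing_edge_rate: float = 0.2
    similarity_signal: float = 0.03
    cross_signal: float = 0.01
    same_score_range: tuple[float, float] = (50.0, 100.0)
    diff_score_range: tuple[float, float] = (30.0, 80.0)
    seed: int = 0

    def __post_init__(self):
        if self.n_proteins < 2 or self.m_labels < 1:
            raise ValidationError("need at least 2 proteins and 1 label")
        if self.labels_per_protein <= 0:
            raise ValidationError("labels_per_protein must be positive")
        for name in ("p_in", "p_out", "spurious_edge_rate", "missing_edge_rate",
                     "similarity_signal", "cross_signal"):
            val = getattr(self, name)
            if not (0.0 <= val <= 1.0):
                raise ValidationError(f"{name} must lie in [0, 1]")
        for rng_name in ("same_score_range", "diff_score_range"):
            lo, hi = getattr(self, rng_name)
            if not (0 < lo <= hi):
                raise ValidationError(f"{rng_name} must satisfy 0 < lo <= hi")


def _protein_names(n: int) -> list[str]:
    width = len(str(n))
    return [f"P{i + 1:0{width}d}" for i in range(n)]


def generate(spec: SyntheticSpec) -> tuple[ProteinNetwork, AnnotationTable, SimilarityMatrix]:
    """Draw one (network, annotations, similarity) triple from a single seed."""
    rng = np.random.default_rng(spec.seed)
    n, m = spec.n_proteins, spec.m_labels
    proteins = _protein_names(n)
    labels = [f"F{j + 1}" for j in range(m)]

    # --- label assignment: shifted Poisson count (1 + Poisson(mean - 1), so
    # the configured mean is exact and every protein has >= 1 label) --------
    counts = np.minimum(1 + rng.poisson(spec.labels_per_protein - 1.0, size=n), m)
    membership = np.zeros((n, m), dtype=bool)
    for i in range(n):
        membership[i, rng.choice(m, size=counts[i], replace=False)] = True

    # --- planted-partition edges ------------------------------------------
    same = (membership @ membership.T) > 0
    iu, ju = np.triu_indices(n, k=1)
    pair_same = same[iu, ju]
    p = np.where(pair_same, spec.p_in, spec.p_out)
    true_edges = rng.random(len(iu)) < p
    true_idx = np.flatnonzero(true_edges)
    n_true = len(true_idx)
    if n_true == 0:
        raise ValidationError("parameter combination yields an empty graph")

    # --- incompleteness: delete a fraction of true edges -------------------
    n_del = int(np.floor(spec.missing_edge_rate * n_true + 0.5))
    delete = set(rng.choice(n_true, size=n_del, replace=False).tolist()) if n_del else set()
    kept_idx = np.array([true_idx[i] for i in range(n_true) if i not in delete], dtype=int)

    # --- noise: add spurious non-edges, rate relative to the true count ----
    n_add = int(np.floor(spec.spurious_edge_rate * n_true + 0.5))
    non_edge_idx = np.flatnonzero(~true_edges)
    if n_add > len(non_edge_idx):
        n_add = len(non_edge_idx)
    added_idx = rng.choice(non_edge_idx, size=n_add, replace=False) if n_add else np.array([], dtype=int)

    edge_idx = np.concatenate([kept_idx, added_idx])
    net = ProteinNetwork.from_edges(
        ((proteins[iu[e]], proteins[ju[e]], 1.0) for e in edge_idx), nodes=proteins
    )

    # --- annotations: full truth ------------------------------------------
    assignments = {
        proteins[i]: {labels[j] for j in range(m) if membership[i, j]} for i in range(n)
    }
    annotations = AnnotationTable(assignments, labels=labels)

    # --- label-correlated sequence similarity ------------------------------
    hit_p = np.where(pair_same, spec.similarity_signal, spec.cross_signal)
    hits = rng.random(len(iu)) < hit_p
    lo = np.where(pair_same, spec.same_score_range[0], spec.diff_score_range[0])
    hi = np.where(pair_same, spec.same_score_range[1], spec.diff_score_range[1])
    draws = lo + rng.random(len(iu)) * (hi - lo)
    pair_scores = np.where(hits, draws, 0.0)
    S = np.zeros((n, n))
    S[iu, ju] = pair_scores
    S = S + S.T
    sim = SimilarityMatrix(proteins, S)

    logger.info(
        "synthetic.generate: n=%d m=%d edges=%d (true=%d, deleted=%d, spurious=%d)",
        n, m, net.n_edges, n_true, n_del, len(added_idx),
    )
    return net, annotations, sim
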