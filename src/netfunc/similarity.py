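"""Pairwise protein similarity indices computed from network topology.

Local indices (common neighbors, Jaccard, FS, FS.R) score a pair by its
neighborhood overlap; global indices score it by walk structure: the Katz
index sums all walks between two nodes, damped geometrically by length
(weight β^L for length L), and random walk with restart (RWR) measures the
steady-state visit probability of a walker that follows edges with
probability c and teleports back to its start with probability 1 − c.

All indices return a :class:`~netfunc.model.SimilarityMatrix`: symmetric,
non-negative, zero diagonal, indexed by the sorted node list.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import scipy.linalg

from .model import ProteinNetwork, SimilarityMatrix, ValidationError

logger = logging.getLogger("netfunc")

INDEX_NAMES = ("cn", "jaccard", "fs", "fsr", "katz", "rwr", "sequence")


class DivergenceError(ValidationError):
    """Katz series diverges for the requested β."""


class ConvergenceError(RuntimeError):
    """Power iteration failed to converge within the iteration budget."""


@dataclass
class IndexSpec:
    """Which similarity index to compute, with its parameters.

    ``katz_beta`` — walk damping β (None → 0.5/ρ(A), always convergent);
    ``katz_max_len`` — optional truncation: when set the Katz series is summed
    only up to that walk length instead of using the closed form;
    ``rwr_c`` — transmit probability c ∈ (0, 1); ``rwr_tol`` — L1 convergence
    tolerance of the power iteration; ``n_avg`` — FS low-degree penalty
    reference (None → mean degree 2|E|/|V|); ``fs_combine`` — how the two
    directional FS terms combine ('product', the default, or 'sum').
    """

    name: str
    katz_beta: float | None = None
    katz_max_len: int | None = None
    rwr_c: float = 0.9
    rwr_tol: float = 1e-10
    rwr_max_iter: int = 100_000
    n_avg: float | None = None
    fs_combine: str = "product"

    def __post_init__(self):
        if self.name not in INDEX_NAMES:
            raise ValidationError(f"unknown index {self.name!r}; expected one of {INDEX_NAMES}")
        if not (0.0 < self.rwr_c < 1.0):
            raise ValidationError("rwr_c must lie in (0, 1)")
        if not (self.rwr_tol > 0):
            raise ValidationError("rwr_tol must be positive")
        if self.n_avg is not None and self.n_avg < 0:
            raise ValidationError("n_avg must be non-negative")
        if self.fs_combine not in ("product", "sum"):
            raise ValidationError("fs_combine must be 'product' or 'sum'")


# ---------------------------------------------------------------------------
# helpers
# ---------------------------------------------------------------------------


def _check_nodes(net: ProteinNetwork, *nodes: str) -> None:
    for u in nodes:
        if not net.has_node(u):
            raise ValidationError(f"unknown node {u!r}")


def _adjacency(net: ProteinNetwork, weighted: bool) -> tuple[list[str], np.ndarray]:
    nodes = list(net.nodes)
    pos = {u: i for i, u in enumerate(nodes)}
    A = np.zeros((len(nodes), len(nodes)))
    for u, v, w in net.edges():
        val = w if weighted else 1.0
        A[pos[u], pos[v]] = A[pos[v], pos[u]] = val
    return nodes, A


def mean_degree(net: ProteinNetwork) -> float:
    """Default n_avg: the average neighbor count 2|E|/|V|."""
    return net.mean_degree()


# ---------------------------------------------------------------------------
# local indices, pairwise
# ---------------------------------------------------------------------------


def common_neighbors(net: ProteinNetwork, u: str, v: str) -> int:
    """|N_u ∩ N_v| with open neighborhoods (a node is not its own neighbor)."""
    _check_nodes(net, u, v)
    if u == v:
        raise ValidationError("common_neighbors requires u != v")
    return len(net.neighbor_set(u) & net.neighbor_set(v))


def jaccard(net: ProteinNetwork, u: str, v: str) -> float:
    """Neighborhood overlap |N_u ∩ N_v| / |N_u ∪ N_v|; 0 for an empty union."""
    _check_nodes(net, u, v)
    if u == v:
        raise ValidationError("jaccard requires u != v")
    nu, nv = net.neighbor_set(u), net.neighbor_set(v)
    union = nu | nv
    return len(nu & nv) / len(union) if union else 0.0


def _fs_factor(inter: float, side_total: float, lam_pen: float) -> float:
    # one directional term: 2·overlap / (exclusive + 2·overlap + penalty),
    # written via side_total = exclusive + overlap
    denom = side_total + inter + lam_pen
    return 2.0 * inter / denom if denom > 0 else 0.0


def _combine(a: float, b: float, how: str) -> float:
    return a * b if how == "product" else a + b


def functional_similarity(
    net: ProteinNetwork,
    u: str,
    v: str,
    n_avg: float | None = None,
    fs_combine: str = "product",
) -> float:
    """FS index: two directional overlap ratios with a low-degree penalty.

    The penalty λ_{u,v} = max(0, n_avg − |N_u|) down-weights pairs whose
    neighborhoods are too small to trust; n_avg defaults to the network's
    mean degree.
    """
    _check_nodes(net, u, v)
    if u == v:
        raise ValidationError("functional_similarity requires u != v")
    if n_avg is None:
        n_avg = mean_degree(net)
    nu, nv = net.neighbor_set(u), net.neighbor_set(v)
    inter = len(nu & nv)
    lam_uv = max(0.0, n_avg - len(nu))
    lam_vu = max(0.0, n_avg - len(nv))
    return _combine(
        _fs_factor(inter, len(nu), lam_uv),
        _fs_factor(inter, len(nv), lam_vu),
        fs_combine,
    )


def fs_weighted(
    net: ProteinNetwork,
    u: str,
    v: str,
    n_avg: float | None = None,
    fs_combine: str = "product",
) -> float:
    """FS.R: the FS index with edge weights read as interaction reliabilities.

    Common-neighbor evidence is Σ_{w∈N_u∩N_v} r_{u,w}·r_{v,w} and each side's
    total is Σ_{w∈N_u} r_{u,w}; with unit weights this reduces exactly to FS.
    """
    _check_nodes(net, u, v)
    if u == v:
        raise ValidationError("fs_weighted requires u != v")
    if n_avg is None:
        n_avg = mean_degree(net)
    nbr_u = dict(net.neighbors(u))
    nbr_v = dict(net.neighbors(v))
    inter = sum(nbr_u[w] * nbr_v[w] for w in nbr_u.keys() & nbr_v.keys())
    s_u = sum(nbr_u.values())
    s_v = sum(nbr_v.values())
    lam_uv = max(0.0, n_avg - len(nbr_u))
    lam_vu = max(0.0, n_avg - len(nbr_v))
    return _combine(
        _fs_factor(inter, s_u, lam_uv),
        _fs_factor(inter, s_v, lam_vu),
        fs_combine,
    )


# ---------------------------------------------------------------------------
# matrix builders
# ---------------------------------------------------------------------------


def _cn_matrix(A: np.ndarray) -> np.ndarray:
    S = A @ A
    np.fill_diagonal(S, 0.0)
    return S


def _jaccard_matrix(A: np.ndarray) -> np.ndarray:
    inter = A @ A
    deg = A.sum(axis=1)
    union = deg[:, None] + deg[None, :] - inter
    with np.errstate(invalid="ignore", divide="ignore"):
        S = np.where(union > 0, inter / np.where(union > 0, union, 1.0), 0.0)
    np.fill_diagonal(S, 0.0)
    return S


def _fs_matrix(A: np.ndarray, W: np.ndarray, n_avg: float, how: str) -> np.ndarray:
    # A is the binary adjacency (neighbor counts drive the λ penalty even in
    # the weighted form); W carries reliabilities for FS.R, W = A for FS.
    inter = W @ W
    side = W.sum(axis=1)
    deg = A.sum(axis=1)
    lam = np.maximum(0.0, n_avg - deg)
    denom_u = side[:, None] + inter + lam[:, None]
    denom_v = side[None, :] + inter + lam[None, :]
    with np.errstate(invalid="ignore", divide="ignore"):
        f_u = np.where(denom_u > 0, 2.0 * inter / np.where(denom_u > 0, denom_u, 1.0), 0.0)
        f_v = np.where(denom_v > 0, 2.0 * inter / np.where(denom_v > 0, denom_v, 1.0), 0.0)
    S = f_u * f_v if how == "product" else f_u + f_v
    np.fill_diagonal(S, 0.0)
    return S


def spectral_radius(A: np.ndarray) -> float:
    if A.shape[0] == 0:
        return 0.0
    return float(np.max(np.abs(np.linalg.eigvalsh(A))))


def katz_matrix(net: ProteinNetwork, spec: IndexSpec | None = None) -> SimilarityMatrix:
    """Katz index on the binary adjacency: S = Σ_{L≥1} β^L A^L.

    Computed in closed form as (I − βA)^{-1} − I, requiring β·ρ(A) < 1;
    β defaults to 0.5/ρ(A).  When ``spec.katz_max_len`` is set the series is
    truncated at that walk length instead.  The diagonal is zeroed afterwards.
    """
    spec = spec or IndexSpec("katz")
    nodes, A = _adjacency(net, weighted=False)
    n = len(nodes)
    rho = spectral_radius(A)
    beta = spec.katz_beta
    if beta is None:
        beta = 0.5 / rho if rho > 0 else 0.5
    if rho > 0 and beta * rho >= 1.0 - 1e-9:
        raise DivergenceError(
            f"Katz series diverges: beta={beta} with spectral radius {rho:.6g}; "
            f"beta must be below {1.0 / rho:.6g}"
        )
    if spec.katz_max_len is not None:
        S = np.zeros((n, n))
        term = np.eye(n)
        for _ in range(spec.katz_max_len):
            term = beta * (term @ A)
            S += term
    else:
        S = scipy.linalg.inv(np.eye(n) - beta * A) - np.eye(n)
    S = (S + S.T) / 2.0  # remove round-off asymmetry
    np.fill_diagonal(S, 0.0)
    S[S < 0] = 0.0  # clip numerical dust; the true series is non-negative
    return SimilarityMatrix(nodes, S)


def rwr_steady_state(net: ProteinNetwork, spec: IndexSpec | None = None) -> tuple[list[str], np.ndarray]:
    """Raw RWR steady states before symmetrization.

    Returns (nodes, R) where column i solves R_i = c·W̃ᵀ·R_i + (1 − c)·e_i by
    power iteration; W̃ is the row-normalized weight matrix.  Columns of
    isolated start nodes are zeroed with a warning.
    """
    spec = spec or IndexSpec("rwr")
    nodes, W = _adjacency(net, weighted=True)
    n = len(nodes)
    if n == 0:
        return nodes, np.zeros((0, 0))
    row_sums = W.sum(axis=1)
    isolated = row_sums == 0
    if isolated.any():
        logger.warning(
            "rwr: %d isolated node(s) assigned all-zero steady-state rows", int(isolated.sum())
        )
    Wt = np.where(isolated[:, None], 0.0, W / np.where(isolated, 1.0, row_sums)[:, None])
    c = spec.rwr_c
    T = c * Wt.T
    R = np.eye(n)
    restart = (1.0 - c) * np.eye(n)
    for _ in range(spec.rwr_max_iter):
        R_next = T @ R + restart
        delta = np.abs(R_next - R).sum(axis=0).max()
        R = R_next
        if delta < spec.rwr_tol:
            break
    else:
        raise ConvergenceError(
            f"RWR power iteration did not converge within {spec.rwr_max_iter} "
            f"iterations (last residual {delta:.3g})"
        )
    # isolated start nodes get all-zero steady states; nothing walks into an
    # isolated node either, so their rows are already zero
    R[:, isolated] = 0.0
    return nodes, R


def rwr_matrix(net: ProteinNetwork, spec: IndexSpec | None = None) -> SimilarityMatrix:
    """RWR similarity: steady-state visit probabilities, mean-symmetrized."""
    nodes, R = rwr_steady_state(net, spec)
    # R[j, i] is the probability mass at j for start node i; average the two
    # directions so consumers see one symmetric contract
    S = (R + R.T) / 2.0
    np.fill_diagonal(S, 0.0)
    S[S < 0] = 0.0
    return SimilarityMatrix(nodes, S)


def compute_similarity(net: ProteinNetwork, spec: IndexSpec) -> SimilarityMatrix:
    """Dispatch over the topological indices; 'sequence' must be loaded from disk."""
    if spec.name == "sequence":
        raise ValidationError(
            "sequence similarity is externally computed; load it with "
            "netfunc.io.read_similarity_matrix"
        )
    if spec.name == "katz":
        return katz_matrix(net, spec)
    if spec.name == "rwr":
        return rwr_matrix(net, spec)
    nodes, A = _adjacency(net, weighted=False)
    if spec.name == "cn":
        S = _cn_matrix(A)
    elif spec.name == "jaccard":
        S = _jaccard_matrix(A)
    else:
        n_avg = spec.n_avg if spec.n_avg is not None else net.mean_degree()
        if spec.name == "fs":
            S = _fs_matrix(A, A, n_avg, spec.fs_combine)
        else:  # fsr
            _, W = _adjacency(net, weighted=True)
            S = _fs_matrix(A, W, n_avg, spec.fs_combine)
    return SimilarityMatrix(nodes, S)
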