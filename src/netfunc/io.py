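"""Readers and writers for the plain-text interchange formats.

Three TSV dialects are used throughout:

* edge lists — two columns (unweighted) or three (weighted), ``#`` comments;
* annotations — protein, semicolon-separated label list;
* similarity matrices — wide (header row/column of ids) or long (u, v, score).

All writers emit deterministic, sorted output so runs diff cleanly.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable

import numpy as np
import yaml

from .model import (
    AnnotationTable,
    ExperimentConfig,
    ParseError,
    ProteinNetwork,
    SimilarityMatrix,
    ValidationError,
)

logger = logging.getLogger("netfunc")


def _data_lines(path: Path) -> Iterable[tuple[int, list[str]]]:
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            yield lineno, line.split("\t") if "\t" in line else line.split()


# ---------------------------------------------------------------------------
# Edge lists
# ---------------------------------------------------------------------------


def read_edge_list(path: str | Path, weighted: bool = False) -> ProteinNetwork:
    """Read a whitespace/tab-separated undirected edge list.

    Duplicate pairs keep the maximum weight; self-loops are dropped with a
    logged warning and count.  Unweighted edges get uniform weight 1.0.
    """
    path = Path(path)
    import networkx as nx

    g = nx.Graph()
    n_self_loops = 0
    for lineno, fields in _data_lines(path):
        if weighted:
            if len(fields) != 3:
                raise ParseError(f"{path}:{lineno}: expected 3 columns, got {len(fields)}")
            u, v, w_str = fields
            try:
                w = float(w_str)
            except ValueError:
                raise ParseError(f"{path}:{lineno}: malformed weight {w_str!r}") from None
            if not (w > 0):
                raise ValidationError(f"{path}:{lineno}: non-positive weight {w}")
        else:
            if len(fields) == 3:
                # tolerate a weight column in unweighted mode by ignoring it
                u, v = fields[0], fields[1]
            elif len(fields) == 2:
                u, v = fields
            else:
                raise ParseError(f"{path}:{lineno}: expected 2 columns, got {len(fields)}")
            w = 1.0
        if u == v:
            n_self_loops += 1
            g.add_node(u)
            continue
        if g.has_edge(u, v):
            w = max(w, g[u][v]["weight"])
        g.add_edge(u, v, weight=w)
    if n_self_loops:
        logger.warning("read_edge_list: dropped %d self-loop(s) from %s", n_self_loops, path)
    return ProteinNetwork(g)


def write_edge_list(net: ProteinNetwork, path: str | Path, weighted: bool = True) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        for u in net.nodes:
            if net.degree(u) == 0:
                # retain isolated nodes via a commented node record
                fh.write(f"#node\t{u}\n")
        for u, v, w in net.edges():
            if weighted:
                fh.write(f"{u}\t{v}\t{w!r}\n")
            else:
                fh.write(f"{u}\t{v}\n")


def _read_isolated_nodes(path: Path) -> list[str]:
    nodes = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#node\t"):
                nodes.append(line.rstrip("\n").split("\t")[1])
    return nodes


def read_network(path: str | Path, weighted: bool = True) -> ProteinNetwork:
    """Read an edge list written by :func:`write_edge_list` (keeps isolated nodes)."""
    net = read_edge_list(path, weighted=weighted)
    g = net.graph
    g.add_nodes_from(_read_isolated_nodes(Path(path)))
    return ProteinNetwork(g)


# ---------------------------------------------------------------------------
# Annotations
# ---------------------------------------------------------------------------


def read_annotations(path: str | Path) -> AnnotationTable:
    """Read a protein<TAB>label;label;... table.

    The label universe is the sorted union of all seen labels.  Empty label
    fields and duplicate protein rows are rejected.
    """
    path = Path(path)
    assignments: dict[str, set[str]] = {}
    for lineno, fields in _data_lines(path):
        if len(fields) != 2:
            raise ParseError(f"{path}:{lineno}: expected 2 columns, got {len(fields)}")
        protein, labs_str = fields
        labs = {lab for lab in labs_str.split(";") if lab}
        if not labs:
            raise ValidationError(f"{path}:{lineno}: protein {protein!r} has no labels")
        if protein in assignments:
            raise ValidationError(f"{path}:{lineno}: duplicate protein row {protein!r}")
        assignments[protein] = labs
    return AnnotationTable(assignments)


def write_annotations(table: AnnotationTable, path: str | Path) -> None:
    with open(path, "w") as fh:
        for protein in table.proteins:
            labs = ";".join(sorted(table.assignments[protein]))
            fh.write(f"{protein}\t{labs}\n")


# ---------------------------------------------------------------------------
# Similarity matrices
# ---------------------------------------------------------------------------


def read_similarity_matrix(path: str | Path) -> SimilarityMatrix:
    """Read a similarity matrix in wide (header) or long (u, v, score) form.

    The diagonal is forced to zero (self-similarity is ignored); asymmetric
    long-form input is symmetrized by the arithmetic mean with a warning.
    """
    path = Path(path)
    rows = list(_data_lines(path))
    if not rows:
        raise ParseError(f"{path}: empty similarity matrix")
    first = rows[0][1]
    is_long = len(first) == 3 and _is_float(first[2])
    return _read_long(path, rows) if is_long else _read_wide(path, rows)


def _is_float(token: str) -> bool:
    try:
        float(token)
        return True
    except ValueError:
        return False


def _read_long(path: Path, rows) -> SimilarityMatrix:
    seen: dict[tuple[str, str], float] = {}
    asym = 0
    for lineno, fields in rows:
        if len(fields) != 3:
            raise ParseError(f"{path}:{lineno}: expected 3 columns, got {len(fields)}")
        u, v, s_str = fields
        try:
            s = float(s_str)
        except ValueError:
            raise ParseError(f"{path}:{lineno}: malformed score {s_str!r}") from None
        if s < 0:
            raise ValidationError(f"{path}:{lineno}: negative score {s}")
        if u == v:
            continue  # self-similarity ignored
        key = (min(u, v), max(u, v))
        if key in seen and seen[key] != s:
            seen[key] = (seen[key] + s) / 2.0
            asym += 1
        else:
            seen[key] = s
    if asym:
        logger.warning(
            "read_similarity_matrix: symmetrized %d asymmetric pair(s) in %s by mean", asym, path
        )
    index = sorted({n for pair in seen for n in pair})
    pos = {n: i for i, n in enumerate(index)}
    scores = np.zeros((len(index), len(index)))
    for (u, v), s in seen.items():
        scores[pos[u], pos[v]] = scores[pos[v], pos[u]] = s
    return SimilarityMatrix(index, scores)


def _read_wide(path: Path, rows) -> SimilarityMatrix:
    header = rows[0][1]
    col_ids = header[1:]  # first cell is a corner label (may be arbitrary)
    n = len(col_ids)
    if n == 0:
        raise ParseError(f"{path}: wide similarity matrix has no columns")
    data_rows = rows[1:]
    if len(data_rows) != n:
        raise ValidationError(
            f"{path}: non-square wide matrix ({len(data_rows)} rows, {n} columns)"
        )
    row_ids = []
    mat = np.zeros((n, n))
    for i, (lineno, fields) in enumerate(data_rows):
        if len(fields) != n + 1:
            raise ParseError(f"{path}:{lineno}: expected {n + 1} columns, got {len(fields)}")
        row_ids.append(fields[0])
        for j, tok in enumerate(fields[1:]):
            try:
                s = float(tok)
            except ValueError:
                raise ParseError(f"{path}:{lineno}: malformed score {tok!r}") from None
            if s < 0:
                raise ValidationError(f"{path}:{lineno}: negative score {s}")
            mat[i, j] = s
    if row_ids != col_ids:
        raise ValidationError(f"{path}: wide-matrix row ids do not match column ids")
    if not np.allclose(mat, mat.T):
        mat = (mat + mat.T) / 2.0
        logger.warning("read_similarity_matrix: symmetrized asymmetric wide matrix %s by mean", path)
    np.fill_diagonal(mat, 0.0)
    order = np.argsort(np.array(col_ids))
    index = [col_ids[i] for i in order]
    return SimilarityMatrix(index, mat[np.ix_(order, order)])


def write_similarity_matrix(sim: SimilarityMatrix, path: str | Path) -> None:
    """Write the wide TSV dialect (header row/column of sorted ids)."""
    with open(path, "w") as fh:
        fh.write("id\t" + "\t".join(sim.index) + "\n")
        for i, node in enumerate(sim.index):
            vals = "\t".join(f"{x:.10g}" for x in sim.scores[i])
            fh.write(f"{node}\t{vals}\n")


# ---------------------------------------------------------------------------
# Config
# ---------------------------------------------------------------------------

_YAML_KEYS = {
    "lambda": "lam",  # YAML uses the field's mathematical name
}


def read_config(path: str | Path) -> ExperimentConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ParseError(f"{path}: config must be a mapping")
    kwargs = {_YAML_KEYS.get(k, k): v for k, v in raw.items()}
    return ExperimentConfig(**kwargs)


def write_config(cfg: ExperimentConfig, path: str | Path) -> None:
    data = {k: v for k, v in cfg.__dict__.items()}
    data["lambda"] = data.pop("lam")
    with open(path, "w") as fh:
        yaml.safe_dump(data, fh, sort_keys=True)
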