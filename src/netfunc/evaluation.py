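"""Experiments and the rank-wise TP/FP accuracy metric.

At rank i, TP counts the proteins whose i-th ranked predicted function is
one of their true functions and FP counts those whose i-th prediction is
not; the ratio TP/FP is the accuracy statistic.  Queries with no voting
evidence (uninformative) are excluded from both counts and reported
separately.

Two protocols are provided: leave-one-out (each annotated protein in turn
is hidden and re-predicted with the deterministic majority method) and the
sparsely-labeled experiment (a seeded fraction of proteins keep their
labels, the rest are predicted collectively by Gibbs sampling; repeated and
averaged).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .inference import RankedPrediction, gibbs_classify, majority_predict
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
class RankRow:
    rank: int
    tp: int
    fp: int
    evaluated: int
    ratio: float  # math.inf marks FP = 0; math.nan marks nothing evaluated


@dataclass
class RankMetrics:
    """Per-rank TP/FP counts plus the count of excluded uninformative queries."""

    rows: list[RankRow]
    n_uninformative: int = 0

    def ratio(self, rank: int) -> float:
        for row in self.rows:
            if row.rank == rank:
                return row.ratio
        raise KeyError(rank)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(r.rank, r.tp, r.fp, r.evaluated, r.ratio) for r in self.rows],
            columns=["rank", "tp", "fp", "evaluated", "ratio"],
        )


def _ratio(tp: int, fp: int, evaluated: int) -> float:
    if evaluated == 0:
        return math.nan
    return tp / fp if fp > 0 else math.inf


def tp_fp_by_rank(
    predictions: dict[str, RankedPrediction],
    truth: AnnotationTable,
    R: int,
) -> RankMetrics:
    """Accumulate rank-wise TP/FP over a prediction map.

    Every predicted protein must have truth labels.  A protein whose ranked
    list is shorter than rank i is excluded at rank i; uninformative
    predictions are excluded everywhere and counted.
    """
    if R < 1:
        raise ValidationError("R must be >= 1")
    tp = np.zeros(R, dtype=int)
    fp = np.zeros(R, dtype=int)
    evaluated = np.zeros(R, dtype=int)
    n_uninformative = 0
    for protein, pred in predictions.items():
        if not truth.is_annotated(protein):
            raise ValidationError(f"protein {protein!r} has no truth labels")
        if pred.uninformative:
            n_uninformative += 1
            continue
        true_set = truth.assignments[protein]
        for i in range(min(R, len(pred.labels))):
            evaluated[i] += 1
            if pred.labels[i] in true_set:
                tp[i] += 1
            else:
                fp[i] += 1
    rows = [
        RankRow(i + 1, int(tp[i]), int(fp[i]), int(evaluated[i]), _ratio(int(tp[i]), int(fp[i]), int(evaluated[i])))
        for i in range(R)
    ]
    return RankMetrics(rows=rows, n_uninformative=n_uninformative)


def choose_ranks(annotations: AnnotationTable) -> int:
    """R = round-half-up of the mean label count per annotated protein, min 1."""
    mean = annotations.mean_labels_per_protein()
    return max(1, int(math.floor(mean + 0.5)))


def leave_one_out(
    net: Network,
    annotations: AnnotationTable,
    cfg: ExperimentConfig | None = None,
) -> RankMetrics:
    """Hide each annotated protein in turn and re-predict it by majority vote.

    Deterministic: the majority method uses no randomness.
    """
    cfg = cfg or ExperimentConfig()
    R = cfg.n_ranks if cfg.n_ranks is not None else choose_ranks(annotations)
    cfg_q = cfg.with_(n_ranks=R)
    nodes = net.nodes if isinstance(net, ProteinNetwork) else net.explicit.nodes
    queries = [p for p in nodes if annotations.is_annotated(p)]
    predictions: dict[str, RankedPrediction] = {}
    for p in queries:
        hidden = annotations.without(p)
        predictions[p] = majority_predict(net, hidden, p, cfg_q)
    return tp_fp_by_rank(predictions, annotations, R)


@dataclass
class SparseLabelResult:
    """Per-repeat metrics and the across-repeat mean/stdev of each rank's ratio."""

    fraction: float
    repeats: list[RankMetrics]
    summary: pd.DataFrame = field(repr=False)

    def mean_ratio(self, rank: int) -> float:
        row = self.summary[self.summary["rank"] == rank]
        if row.empty:
            raise KeyError(rank)
        return float(row["mean_ratio"].iloc[0])


def sparse_label_experiment(
    net: Network,
    annotations: AnnotationTable,
    cfg: ExperimentConfig,
) -> SparseLabelResult:
    """Sparsely-labeled protocol at cfg.annotated_fraction, cfg.n_repeats times.

    Per repeat, a seeded uniform sample of the annotated proteins keeps its
    labels; the rest become queries for :func:`gibbs_classify` and are scored
    against their hidden truth.  The mean of per-repeat ratios (not the ratio
    of pooled counts) is reported per rank, with its standard deviation.
    """
    f = cfg.annotated_fraction
    nodes = set(net.nodes if isinstance(net, ProteinNetwork) else net.explicit.nodes)
    annotated = sorted(p for p in annotations.proteins if p in nodes)
    if not annotated:
        raise ValidationError("no annotated proteins in the network")
    n_keep = int(math.floor(f * len(annotated) + 0.5))
    if n_keep < 1:
        raise ValidationError(f"fraction {f} keeps no annotated protein")
    if n_keep >= len(annotated):
        raise ValidationError(f"fraction {f} leaves no query protein")
    R = cfg.n_ranks if cfg.n_ranks is not None else choose_ranks(annotations)

    seed_seq = np.random.SeedSequence(cfg.seed)
    repeat_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in seed_seq.spawn(cfg.n_repeats)]

    repeats: list[RankMetrics] = []
    n_predictions = 0
    for rep, rep_seed in enumerate(repeat_seeds):
        rng = np.random.default_rng(rep_seed)
        keep = set(rng.choice(len(annotated), size=n_keep, replace=False).tolist())
        retained = [annotated[i] for i in sorted(keep)]
        hidden = [p for i, p in enumerate(annotated) if i not in keep]
        visible = annotations.restrict(retained)
        result = gibbs_classify(net, visible, cfg.with_(seed=rep_seed, n_ranks=R))
        preds = {p: result[p] for p in hidden if p in result}
        n_predictions += len(preds)
        repeats.append(tp_fp_by_rank(preds, annotations, R))
    logger.info(
        "sparse_label_experiment: fraction=%.2f repeats=%d predictions=%d",
        f, cfg.n_repeats, n_predictions,
    )

    records = []
    for rank in range(1, R + 1):
        ratios = np.array([rep.ratio(rank) for rep in repeats])
        finite = ratios[np.isfinite(ratios)]
        mean = float(np.mean(ratios)) if len(ratios) else math.nan
        std = float(np.std(finite, ddof=1)) if len(finite) > 1 else math.nan
        records.append((rank, mean, std, int(np.sum(np.isinf(ratios)))))
    summary = pd.DataFrame(records, columns=["rank", "mean_ratio", "std_ratio", "n_infinite"])
    return SparseLabelResult(fraction=f, repeats=repeats, summary=summary)
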