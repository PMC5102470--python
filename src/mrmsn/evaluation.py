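"""Confusion-matrix metrics and AUROC over undirected gene pairs.

An inferred network is compared with a gold standard by classifying every
one of the n(n-1)/2 unordered gene pairs as edge / non-edge.  The derived
rates are

    TPR = TP / (TP + FN)        FPR = FP / (FP + TN)
    PPV = TP / (TP + FP)        ACC = (TP + TN) / (TP + FP + TN + FN)

AUROC ranks all pairs by a continuous edge score and equals the probability
that a random gold edge outranks a random non-edge (ties count half).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations
from typing import Mapping, Optional

import networkx as nx
from sklearn.metrics import roc_auc_score

__all__ = ["EvaluationReport", "confusion", "metrics", "auroc", "evaluate"]


@dataclass
class EvaluationReport:
    tp: int
    fp: int
    tn: int
    fn: int
    tpr: float = 0.0
    fpr: float = 0.0
    ppv: float = 0.0
    acc: float = 0.0
    auroc: Optional[float] = None

    def as_row(self) -> str:
        cells = [self.tp, self.fp, self.tn, self.fn]
        cells += [f"{v:.3f}" for v in (self.tpr, self.fpr, self.ppv, self.acc)]
        if self.auroc is not None:
            cells.append(f"{self.auroc:.3f}")
        return "\t".join(str(c) for c in cells)


def _pair_set(g: nx.Graph) -> set:
    return {frozenset(e) for e in g.edges if e[0] != e[1]}


def confusion(predicted: nx.Graph, gold: nx.Graph) -> EvaluationReport:
    """Count TP/FP/TN/FN over all unordered pairs of the shared gene set."""
    if set(predicted.nodes) != set(gold.nodes):
        raise ValueError("predicted and gold networks cover different gene sets")
    nodes = sorted(predicted.nodes)
    pred = _pair_set(predicted)
    true = _pair_set(gold)
    tp = fp = tn = fn = 0
    for a, b in combinations(nodes, 2):
        pair = frozenset((a, b))
        if pair in true:
            if pair in pred:
                tp += 1
            else:
                fn += 1
        else:
            if pair in pred:
                fp += 1
            else:
                tn += 1
    return EvaluationReport(tp=tp, fp=fp, tn=tn, fn=fn)


def metrics(tp: int, fp: int, tn: int, fn: int) -> EvaluationReport:
    """Derive TPR/FPR/PPV/ACC from confusion counts."""
    report = EvaluationReport(tp=tp, fp=fp, tn=tn, fn=fn)
    report.tpr = tp / (tp + fn) if tp + fn else 0.0
    report.fpr = fp / (fp + tn) if fp + tn else 0.0
    if tp + fp:
        report.ppv = tp / (tp + fp)
    else:
        warnings.warn("no predicted edges; PPV reported as 0", stacklevel=2)
        report.ppv = 0.0
    report.acc = (tp + tn) / (tp + fp + tn + fn)
    return report


def auroc(scores: Mapping, gold: nx.Graph) -> float:
    """Rank-based AUROC of pair scores against the gold edge set.

    Equivalent to the normalized Mann-Whitney U statistic comparing the
    scores of gold edges with those of non-edges; tied scores contribute
    one half.  Pairs absent from ``scores`` are treated as score 0.
    """
    nodes = sorted(gold.nodes)
    true = _pair_set(gold)
    lookup = {frozenset(k): v for k, v in scores.items()}
    y_true, y_score = [], []
    for a, b in combinations(nodes, 2):
        pair = frozenset((a, b))
        y_true.append(1 if pair in true else 0)
        y_score.append(float(lookup.get(pair, 0.0)))
    if sum(y_true) == 0 or sum(y_true) == len(y_true):
        raise ValueError("AUROC undefined: gold network is empty or complete")
    return float(roc_auc_score(y_true, y_score))


def evaluate(
    predicted: nx.Graph, gold: nx.Graph, scores: Optional[Mapping] = None
) -> EvaluationReport:
    """Full report: confusion counts, the four rates, and AUROC if scores
    are supplied."""
    counts = confusion(predicted, gold)
    report = metrics(counts.tp, counts.fp, counts.tn, counts.fn)
    if scores is not None:
        report.auroc = auroc(scores, gold)
    return report
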