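"""Precision/recall of a predicted subnetwork against a gold standard.

Precision = TP / all-predicted-positive; recall = TP / all-true-positive,
computed separately for nodes and for edges (edges matched by id).  An
empty ratio (0/0) is 1.0 for precision — an empty prediction claims
nothing falsely — while recall against a nonempty gold standard is 0.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

from .scoring import Selection


@dataclass(frozen=True)
class PRResult:
    node_precision: float
    node_recall: float
    edge_precision: float
    edge_recall: float

    def to_dict(self) -> dict:
        return asdict(self)


def _ratio(numerator: int, denominator: int) -> float:
    if denominator == 0:
        return 1.0
    return numerator / denominator


def precision_recall(
    predicted: Selection, gold_nodes: set[str], gold_edges: set[str]
) -> PRResult:
    """Node and edge precision/recall of a selection against the gold sets."""
    pred_nodes = predicted.node_set()
    pred_edges = predicted.edge_set()
    node_tp = len(pred_nodes & gold_nodes)
    edge_tp = len(pred_edges & gold_edges)
    return PRResult(
        node_precision=_ratio(node_tp, len(pred_nodes)),
        node_recall=_ratio(node_tp, len(gold_nodes)),
        edge_precision=_ratio(edge_tp, len(pred_edges)),
        edge_recall=_ratio(edge_tp, len(gold_edges)),
    )


def mean_pr(results: list[PRResult]) -> PRResult:
    """Arithmetic mean of per-replicate metrics."""
    if not results:
        raise ValueError("no results to average")
    n = len(results)
    return PRResult(
        node_precision=sum(r.node_precision for r in results) / n,
        node_recall=sum(r.node_recall for r in results) / n,
        edge_precision=sum(r.edge_precision for r in results) / n,
        edge_recall=sum(r.edge_recall for r in results) / n,
    )
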