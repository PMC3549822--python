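"""Node and edge scoring and the linear subnetwork objective.

Node profit follows the beta-uniform-mixture score

    W_n = (a - 1) * (log p_n - log tau)

with shape parameter a in [0, 1] and size threshold tau: the profit is
positive exactly when p < tau (for a < 1), so tau controls how many nodes
score positively and hence the size of the selected subnetwork.  Node cost
is the log of the number of distinct neighbors, C_n = log D, penalising
hubs.  Edge consistency W_e rewards directed edges that explain the
observed directions of regulation (+2 consistent, -1 partially informative,
-2 contradicted) and assigns a constant weight (default -1) to undirected
binding and to ptm edges, whose sign is unknown.  The edge score is
S_e = W_e * C_e with C_e the curated confidence.  Profits, costs and edge
scores are each standardized by the maximum absolute value of their class,
mapping into [-1, 1], and combine into the subnetwork objective

    S = sum_n x_n (alpha W'_n - beta_n C'_n) + gamma sum_e x_e S'_e

where beta_n switches between two values by the sign of the node's profit:
by default positively scoring nodes pay no connectivity cost (beta = 0)
while negatively scoring nodes pay full cost (beta = 1), so that
well-studied highly connected DE genes are not squeezed out.
Natural logarithms are used throughout.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

from .model import (
    Direction,
    EdgeType,
    ExpressionData,
    InteractionNetwork,
)


@dataclass(frozen=True)
class ScoringParams:
    """Scoring constants.

    a : shape parameter of the beta-uniform mixture, in [0, 1]; a = 0 gives
        the simplified score -(log p - log tau).
    tau : p-value threshold at which node profit changes sign, in (0, 1).
    alpha, gamma : scale factors of node profit and edge score in the objective.
    beta_positive, beta_negative : connectivity-cost scale for nodes with
        nonnegative / negative standardized profit.
    undirected_edge_weight : constant consistency weight of binding and ptm edges.
    missing_gene_penalty : |constant| profit deficit of network genes absent
        from the expression table (applied as -missing_gene_penalty).
    """

    a: float = 0.0
    tau: float = 0.05
    alpha: float = 1.0
    beta_positive: float = 0.0
    beta_negative: float = 1.0
    gamma: float = 1.0
    undirected_edge_weight: float = -1.0
    missing_gene_penalty: float = 1.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.a <= 1.0:
            raise ValueError(f"shape parameter a={self.a} outside [0, 1]")
        if not 0.0 < self.tau < 1.0:
            raise ValueError(f"tau={self.tau} outside (0, 1)")
        if self.missing_gene_penalty <= 0:
            raise ValueError("missing_gene_penalty must be positive")
        for name in ("alpha", "beta_positive", "beta_negative", "gamma"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")

    def to_dict(self) -> dict:
        return asdict(self)


def node_profit(p: float, a: float, tau: float) -> float:
    """Significance profit W_n = (a - 1)(log p - log tau), natural log.

    Positive iff p < tau (for a < 1); zero at p = tau or a = 1.
    """
    if p <= 0.0 or p > 1.0:
        raise ValueError(f"p-value {p} outside (0, 1]")
    if not 0.0 < tau < 1.0:
        raise ValueError(f"tau {tau} outside (0, 1)")
    if not 0.0 <= a <= 1.0:
        raise ValueError(f"shape parameter {a} outside [0, 1]")
    return (a - 1.0) * (math.log(p) - math.log(tau))


def node_cost(degree: int) -> float:
    """Connectivity cost C_n = log D over distinct neighbors; 0 for isolated nodes."""
    if degree < 0:
        raise ValueError(f"negative degree {degree}")
    if degree == 0:
        return 0.0
    return math.log(degree)


def edge_consistency(
    edge_type: EdgeType,
    d_source: Direction,
    d_target: Direction,
    undirected_edge_weight: float = -1.0,
) -> float:
    """Consistency weight W_e of an edge given its endpoint directions.

    Activation: +2 if both endpoints changed in the same direction, -2 if
    changed in opposite directions, -1 if either endpoint is unchanged.
    Inhibition: +2 if changed in opposite directions, -2 if in the same
    direction, -1 otherwise (at least one endpoint unchanged).
    Binding and ptm edges get the constant ``undirected_edge_weight``
    regardless of directions.
    """
    if edge_type in (EdgeType.BINDING, EdgeType.PTM):
        return undirected_edge_weight
    src_changed = d_source is not Direction.UNCHANGED
    tgt_changed = d_target is not Direction.UNCHANGED
    if edge_type is EdgeType.ACTIVATION:
        if not (src_changed and tgt_changed):
            return -1.0
        return 2.0 if d_source is d_target else -2.0
    if edge_type is EdgeType.INHIBITION:
        if not (src_changed and tgt_changed):
            return -1.0
        return 2.0 if d_source is not d_target else -2.0
    raise ValueError(f"unknown edge type {edge_type!r}")


@dataclass
class ScoredNetwork:
    """A network with all raw and standardized node/edge scores attached."""

    network: InteractionNetwork
    expression: ExpressionData
    params: ScoringParams
    node_profit: dict[str, float]
    node_cost: dict[str, float]
    node_profit_std: dict[str, float]
    node_cost_std: dict[str, float]
    edge_consistency: dict[str, float]
    edge_score: dict[str, float]
    edge_score_std: dict[str, float]

    def node_objective_coefficient(self, node: str) -> float:
        """alpha * W'_n - beta_n * C'_n with beta_n chosen by profit sign."""
        p = self.params
        w = self.node_profit_std[node]
        beta = p.beta_positive if w >= 0 else p.beta_negative
        return p.alpha * w - beta * self.node_cost_std[node]

    def edge_objective_coefficient(self, edge_id: str) -> float:
        return self.params.gamma * self.edge_score_std[edge_id]


@dataclass
class Selection:
    """Boolean selection variables x_n, x_e over a scored network."""

    selected_nodes: dict[str, bool]
    selected_edges: dict[str, bool]

    @classmethod
    def empty(cls, network: InteractionNetwork) -> "Selection":
        return cls(
            {n: False for n in network.nodes},
            {e.edge_id: False for e in network.edges},
        )

    def node_set(self) -> set[str]:
        return {n for n, v in self.selected_nodes.items() if v}

    def edge_set(self) -> set[str]:
        return {e for e, v in self.selected_edges.items() if v}


def _standardize(raw: dict[str, float]) -> dict[str, float]:
    """Divide by max |value|; all-zero classes stay all zero."""
    m = max((abs(v) for v in raw.values()), default=0.0)
    if m == 0.0:
        return {k: 0.0 for k in raw}
    return {k: v / m for k, v in raw.items()}


def score_network(
    network: InteractionNetwork,
    expr: ExpressionData,
    params: ScoringParams | None = None,
    nca_mode: bool = False,
) -> ScoredNetwork:
    """Compute all node and edge scores for a network against expression data.

    Genes present in the network but absent from the expression table get
    profit -missing_gene_penalty and direction "unchanged".  With
    ``nca_mode`` (the node-centric ablation) every edge is treated as an
    undirected edge with consistency +1, so edge type and direction carry
    no information and only confidences differentiate edges.
    """
    if params is None:
        params = ScoringParams()
    if network.n_nodes == 0:
        raise ValueError("cannot score an empty network")

    profits: dict[str, float] = {}
    costs: dict[str, float] = {}
    for n in network.nodes:
        p = expr.p_value_of(n)
        if p is None:
            profits[n] = -abs(params.missing_gene_penalty)
        else:
            profits[n] = node_profit(p, params.a, params.tau)
        costs[n] = node_cost(network.degree(n))

    consistencies: dict[str, float] = {}
    scores: dict[str, float] = {}
    for e in network.edges:
        if nca_mode:
            w = 1.0
        else:
            w = edge_consistency(
                e.edge_type,
                expr.direction_of(e.source),
                expr.direction_of(e.target),
                params.undirected_edge_weight,
            )
        consistencies[e.edge_id] = w
        scores[e.edge_id] = w * e.confidence

    return ScoredNetwork(
        network=network,
        expression=expr,
        params=params,
        node_profit=profits,
        node_cost=costs,
        node_profit_std=_standardize(profits),
        node_cost_std=_standardize(costs),
        edge_consistency=consistencies,
        edge_score=scores,
        edge_score_std=_standardize(scores),
    )


def subnetwork_score(scored: ScoredNetwork, sel: Selection) -> float:
    """Evaluate the subnetwork objective S on a selection.

    S = sum over selected nodes of (alpha W'_n - beta_n C'_n) plus gamma
    times the sum of standardized scores of selected edges.
    """
    if set(sel.selected_nodes) != scored.network.nodes or set(sel.selected_edges) != {
        e.edge_id for e in scored.network.edges
    }:
        raise ValueError("selection keys do not match the scored network")
    total = 0.0
    for n, on in sel.selected_nodes.items():
        if on:
            total += scored.node_objective_coefficient(n)
    for eid, on in sel.selected_edges.items():
        if on:
            total += scored.edge_objective_coefficient(eid)
    return total
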