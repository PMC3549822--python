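import numpy as np
import pytest

from asnfinder.model import (
    Direction,
    Edge,
    EdgeType,
    ExpressionData,
    ExpressionRecord,
    InteractionNetwork,
)
from asnfinder.scoring import ScoredNetwork, ScoringParams


def make_scored(
    node_scores: dict[str, float],
    edge_specs: list[tuple[str, str, str, float]],
    node_costs: dict[str, float] | None = None,
    params: ScoringParams | None = None,
) -> ScoredNetwork:
    """Build a ScoredNetwork with prescribed *standardized* scores.

    edge_specs: (edge_id, source, target, standardized score); edges are
    created as activation edges with confidence 1 (the type is irrelevant
    once scores are fixed).
    """
    nodes = set(node_scores)
    edges = [
        Edge(eid, s, t, EdgeType.ACTIVATION, 1.0) for eid, s, t, _ in edge_specs
    ]
    net = InteractionNetwork(nodes, edges)
    expr = ExpressionData([], 0.05)
    costs = node_costs or {n: 0.0 for n in nodes}
    escore = {eid: sc for eid, _, _, sc in edge_specs}
    return ScoredNetwork(
        network=net,
        expression=expr,
        params=params or ScoringParams(),
        node_profit=dict(node_scores),
        node_cost=dict(costs),
        node_profit_std=dict(node_scores),
        node_cost_std=dict(costs),
        edge_consistency=dict(escore),
        edge_score=dict(escore),
        edge_score_std=dict(escore),
    )


def random_scored(rng: np.random.Generator, max_nodes: int = 8, max_edges: int = 12) -> ScoredNetwork:
    """A random small scored network for solver/oracle cross-checks."""
    n = int(rng.integers(2, max_nodes + 1))
    m = int(rng.integers(0, max_edges + 1))
    names = [f"n{i}" for i in range(n)]
    node_scores = {v: float(rng.uniform(-1, 1)) for v in names}
    costs = {v: float(rng.uniform(0, 1)) for v in names}
    specs = []
    for j in range(m):
        s, t = rng.choice(n, size=2, replace=False)
        specs.append((f"e{j}", names[s], names[t], float(rng.uniform(-1, 1))))
    params = ScoringParams(
        alpha=float(rng.uniform(0.2, 2.0)),
        beta_positive=float(rng.uniform(0, 1)),
        beta_negative=float(rng.uniform(0, 2)),
        gamma=float(rng.uniform(0.2, 2.0)),
    )
    return make_scored(node_scores, specs, node_costs=costs, params=params)


@pytest.fixture
def toy_network() -> InteractionNetwork:
    """Three genes: A activates B, B inhibits C, A binds C."""
    return InteractionNetwork(
        {"A", "B", "C"},
        [
            Edge("e1", "A", "B", EdgeType.ACTIVATION, 0.9),
            Edge("e2", "B", "C", EdgeType.INHIBITION, 0.8),
            Edge("e3", "A", "C", EdgeType.BINDING, 0.5),
        ],
    )


@pytest.fixture
def toy_expression() -> ExpressionData:
    return ExpressionData(
        [
            ExpressionRecord("A", 0.001, Direction.UP),
            ExpressionRecord("B", 0.01, Direction.UP),
            ExpressionRecord("C", 0.02, Direction.DOWN),
        ],
        significance_threshold=0.05,
    )
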