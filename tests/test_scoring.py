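"""Node/edge scoring rules, standardization, and the subnetwork objective."""

import math

import pytest
from hypothesis import given, settings, strategies as st

from asnfinder.model import (
    Direction,
    Edge,
    EdgeType,
    ExpressionData,
    ExpressionRecord,
    InteractionNetwork,
)
from asnfinder.scoring import (
    ScoringParams,
    Selection,
    edge_consistency,
    node_cost,
    node_profit,
    score_network,
    subnetwork_score,
)
from conftest import make_scored

UP, DOWN, UNCH = Direction.UP, Direction.DOWN, Direction.UNCHANGED


class TestNodeProfit:
    def test_zero_at_threshold(self):
        assert node_profit(0.05, a=0.0, tau=0.05) == pytest.approx(0.0)

    def test_hand_evaluated_value(self):
        # (0 - 1) * (ln 0.001 - ln 0.05) = ln(0.05/0.001) = ln 50
        assert node_profit(0.001, a=0.0, tau=0.05) == pytest.approx(3.912023, abs=1e-6)

    def test_degenerate_shape_parameter_gives_zero(self):
        assert node_profit(0.2, a=1.0, tau=0.05) == 0.0

    def test_positive_iff_significant(self):
        assert node_profit(0.01, 0.0, 0.05) > 0
        assert node_profit(0.5, 0.0, 0.05) < 0

    @pytest.mark.parametrize("p", [0.0, -0.1, 1.1])
    def test_domain_error(self, p):
        with pytest.raises(ValueError):
            node_profit(p, 0.0, 0.05)

    @given(
        p1=st.floats(1e-12, 1.0, exclude_max=True),
        p2=st.floats(1e-12, 1.0, exclude_max=True),
        a=st.floats(0.0, 1.0, exclude_max=True),
    )
    @settings(derandomize=True, deadline=None)
    def test_strictly_decreasing_in_p(self, p1, p2, a):
        if p1 == p2:
            return
        lo, hi = min(p1, p2), max(p1, p2)
        assert node_profit(lo, a, 0.05) > node_profit(hi, a, 0.05)


class TestNodeCost:
    @pytest.mark.parametrize(
        "degree,expected", [(0, 0.0), (1, 0.0), (10, 2.302585)]
    )
    def test_log_degree(self, degree, expected):
        assert node_cost(degree) == pytest.approx(expected, abs=1e-6)

    def test_negative_degree_rejected(self):
        with pytest.raises(ValueError):
            node_cost(-1)


class TestEdgeConsistency:
    @pytest.mark.parametrize(
        "etype,ds,dt,expected",
        [
            (EdgeType.ACTIVATION, UP, UP, 2.0),
            (EdgeType.ACTIVATION, DOWN, DOWN, 2.0),
            (EdgeType.ACTIVATION, UP, DOWN, -2.0),
            (EdgeType.ACTIVATION, DOWN, UP, -2.0),
            (EdgeType.ACTIVATION, UP, UNCH, -1.0),
            (EdgeType.ACTIVATION, UNCH, DOWN, -1.0),
            (EdgeType.ACTIVATION, UNCH, UNCH, -1.0),
            (EdgeType.INHIBITION, UP, DOWN, 2.0),
            (EdgeType.INHIBITION, DOWN, UP, 2.0),
            (EdgeType.INHIBITION, UP, UP, -2.0),
            (EdgeType.INHIBITION, DOWN, DOWN, -2.0),
            (EdgeType.INHIBITION, UP, UNCH, -1.0),
            (EdgeType.INHIBITION, UNCH, UNCH, -1.0),
            (EdgeType.BINDING, UP, DOWN, -1.0),
            (EdgeType.PTM, UP, UP, -1.0),
        ],
    )
    def test_rule_table(self, etype, ds, dt, expected):
        assert edge_consistency(etype, ds, dt) == expected

    def test_undirected_weight_configurable(self):
        assert edge_consistency(EdgeType.BINDING, UP, UP, undirected_edge_weight=1.0) == 1.0

    @pytest.mark.parametrize("etype", [EdgeType.ACTIVATION, EdgeType.INHIBITION])
    @pytest.mark.parametrize("ds,dt", [(UP, UP), (UP, DOWN), (UP, UNCH), (UNCH, DOWN)])
    def test_symmetric_under_double_flip(self, etype, ds, dt):
        assert edge_consistency(etype, ds, dt) == edge_consistency(
            etype, ds.flipped(), dt.flipped()
        )


class TestScoreNetwork:
    def test_standardization_divides_by_max_abs(self):
        net = InteractionNetwork(
            {"A", "B"}, [Edge("e", "A", "B", EdgeType.ACTIVATION, 1.0)]
        )
        expr = ExpressionData(
            [
                # profits ln(tau/p): pick p's giving raw profits +2 and -4
                ExpressionRecord("A", 0.005 * math.exp(-2), UP),
                ExpressionRecord("B", 0.005 * math.exp(4), UNCH),
            ],
            significance_threshold=0.05,
        )
        scored = score_network(net, expr, ScoringParams(tau=0.005))
        assert scored.node_profit_std["A"] == pytest.approx(0.5)
        assert scored.node_profit_std["B"] == pytest.approx(-1.0)

    def test_edge_score_is_consistency_times_confidence(self, toy_expression):
        net = InteractionNetwork(
            {"A", "B"}, [Edge("e", "A", "B", EdgeType.ACTIVATION, 0.9)]
        )
        scored = score_network(net, toy_expression)
        assert scored.edge_score["e"] == pytest.approx(1.8)
        assert scored.edge_score_std["e"] == pytest.approx(1.0)

    def test_missing_gene_gets_constant_penalty(self, toy_expression):
        net = InteractionNetwork(
            {"A", "X"}, [Edge("e", "A", "X", EdgeType.BINDING, 1.0)]
        )
        scored = score_network(net, toy_expression, ScoringParams(missing_gene_penalty=1.5))
        assert scored.node_profit["X"] == -1.5

    def test_nca_mode_scores_every_edge_plus_one(self, toy_network, toy_expression):
        scored = score_network(toy_network, toy_expression, nca_mode=True)
        for e in toy_network.edges:
            assert scored.edge_consistency[e.edge_id] == 1.0
            assert scored.edge_score[e.edge_id] == pytest.approx(e.confidence)

    def test_all_zero_edge_scores_standardize_to_zero(self):
        net = InteractionNetwork(
            {"A", "B"}, [Edge("e", "A", "B", EdgeType.BINDING, 1.0)]
        )
        expr = ExpressionData([ExpressionRecord("A", 0.01, UP)], 0.05)
        scored = score_network(net, expr, ScoringParams(undirected_edge_weight=0.0))
        assert scored.edge_score_std["e"] == 0.0

    def test_standardized_bounds_and_extremum(self, toy_network, toy_expression):
        scored = score_network(toy_network, toy_expression)
        assert all(-1 <= v <= 1 for v in scored.node_profit_std.values())
        assert all(-1 <= v <= 1 for v in scored.edge_score_std.values())
        assert max(abs(v) for v in scored.node_profit_std.values()) == pytest.approx(1.0)
        assert max(abs(v) for v in scored.edge_score_std.values()) == pytest.approx(1.0)

    def test_empty_network_rejected(self, toy_expression):
        with pytest.raises(ValueError):
            score_network(InteractionNetwork(set(), []), toy_expression)

    @given(scale=st.floats(0.1, 100.0))
    @settings(derandomize=True, deadline=None)
    def test_standardization_scale_invariance(self, scale):
        raw = {"A": 2.0, "B": -4.0, "C": 1.0}
        from asnfinder.scoring import _standardize

        base = _standardize(raw)
        scaled = _standardize({k: v * scale for k, v in raw.items()})
        for k in raw:
            assert scaled[k] == pytest.approx(base[k], abs=1e-12)


class TestSubnetworkScore:
    def test_empty_selection_is_zero(self):
        scored = make_scored({"A": 1.0, "B": 0.4}, [("e", "A", "B", 1.0)])
        assert subnetwork_score(scored, Selection.empty(scored.network)) == 0.0

    def test_hand_evaluated_objective(self):
        scored = make_scored({"A": 1.0, "B": 0.4}, [("e", "A", "B", 1.0)])
        sel = Selection({"A": True, "B": True}, {"e": True})
        assert subnetwork_score(scored, sel) == pytest.approx(2.4)

    def test_gamma_zero_drops_edge_term(self):
        scored = make_scored(
            {"A": 1.0, "B": 0.4},
            [("e", "A", "B", 1.0)],
            params=ScoringParams(gamma=0.0),
        )
        sel = Selection({"A": True, "B": True}, {"e": True})
        assert subnetwork_score(scored, sel) == pytest.approx(1.4)

    def test_beta_switches_on_profit_sign(self):
        scored = make_scored(
            {"A": -0.5, "B": 0.5},
            [("e", "A", "B", 0.0)],
            node_costs={"A": 1.0, "B": 1.0},
            params=ScoringParams(beta_positive=0.0, beta_negative=1.0),
        )
        sel = Selection({"A": True, "B": True}, {"e": True})
        # A pays its cost (negative profit), B does not
        assert subnetwork_score(scored, sel) == pytest.approx(-0.5 - 1.0 + 0.5)

    def test_mismatched_keys_rejected(self):
        scored = make_scored({"A": 1.0, "B": 0.4}, [("e", "A", "B", 1.0)])
        with pytest.raises(ValueError):
            subnetwork_score(scored, Selection({"A": True}, {"e": False}))

    def test_additive_over_disjoint_selections(self):
        scored = make_scored(
            {"A": 1.0, "B": 0.4, "C": -0.2, "D": 0.7},
            [("e1", "A", "B", 1.0), ("e2", "C", "D", -0.5)],
        )
        s1 = Selection(
            {"A": True, "B": True, "C": False, "D": False},
            {"e1": True, "e2": False},
        )
        s2 = Selection(
            {"A": False, "B": False, "C": True, "D": True},
            {"e1": False, "e2": True},
        )
        union = Selection(
            {n: s1.selected_nodes[n] or s2.selected_nodes[n] for n in scored.network.nodes},
            {e: s1.selected_edges[e] or s2.selected_edges[e] for e in s1.selected_edges},
        )
        assert subnetwork_score(scored, union) == pytest.approx(
            subnetwork_score(scored, s1) + subnetwork_score(scored, s2)
        )
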