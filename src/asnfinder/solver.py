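"""Boolean integer program selecting the maximum-score subnetwork.

Variables x_n, x_e in {0, 1} maximize the linear subnetwork objective
subject to the coupling constraints

    (a) x_n <= sum of x_e over edges incident to n (either orientation):
        a selected node must touch at least one selected edge;
    (b) x_e <= x_source and (c) x_e <= x_target:
        a selected edge requires both endpoints.

The constraints make the empty selection feasible, so the optimum is always
>= 0.  They do not force connectedness; connected components of the
selected subgraph are reported, and callers may keep only the best one.
Together (a)-(c) make the node set a function of the edge set — exactly the
endpoints of the selected edges — which the brute-force oracle exploits.

The backend is the HiGHS mixed-integer solver via ``scipy.optimize.milp``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import Bounds, LinearConstraint, milp
from scipy.sparse import lil_matrix

from .scoring import ScoredNetwork, Selection, subnetwork_score

#: objective must match an independent evaluation this closely
OBJECTIVE_ATOL = 1e-6


@dataclass(frozen=True)
class SolverOptions:
    backend: str = "highs"
    time_limit: float = 300.0
    mip_gap: float = 0.0
    require_components_report: bool = True

    def __post_init__(self) -> None:
        if self.time_limit <= 0:
            raise ValueError("time_limit must be positive")
        if self.mip_gap < 0:
            raise ValueError("mip_gap must be nonnegative")


@dataclass
class ASNResult:
    """Solved selection with its objective, solver status and components."""

    selection: Selection
    objective: float
    status: str  # optimal | feasible_timeout | infeasible_guarded
    components: list[set[str]] = field(default_factory=list)


class SolverConfigurationError(ValueError):
    pass


class SolverFailure(RuntimeError):
    pass


def solve_asn(scored: ScoredNetwork, opts: SolverOptions | None = None) -> ASNResult:
    """Find the selection maximizing the subnetwork objective.

    Returns the optimal selection, or the best incumbent with status
    ``feasible_timeout`` if the time limit is hit.  The reported objective
    is recomputed from the returned selection, not read off the solver.
    """
    if opts is None:
        opts = SolverOptions()
    if opts.backend != "highs":
        raise SolverConfigurationError(
            f"unknown solver backend {opts.backend!r} (supported: 'highs')"
        )
    net = scored.network
    nodes = sorted(net.nodes)
    edges = net.edges
    n, m = len(nodes), len(edges)
    node_idx = {v: i for i, v in enumerate(nodes)}
    edge_idx = {e.edge_id: n + j for j, e in enumerate(edges)}

    # milp minimizes: negate the profit coefficients.
    c = np.zeros(n + m)
    for v in nodes:
        c[node_idx[v]] = -scored.node_objective_coefficient(v)
    for e in edges:
        c[edge_idx[e.edge_id]] = -scored.edge_objective_coefficient(e.edge_id)

    n_rows = n + 2 * m
    A = lil_matrix((n_rows, n + m))
    row = 0
    for v in nodes:  # (a)  x_n - sum_incident x_e <= 0
        A[row, node_idx[v]] = 1.0
        for e in net.incident_edges(v):
            A[row, edge_idx[e.edge_id]] -= 1.0
        row += 1
    for e in edges:  # (b), (c)  x_e - x_endpoint <= 0
        for endpoint in (e.source, e.target):
            A[row, edge_idx[e.edge_id]] = 1.0
            A[row, node_idx[endpoint]] += -1.0
            row += 1

    res = milp(
        c,
        constraints=LinearConstraint(A.tocsr(), -np.inf, 0.0),
        integrality=np.ones(n + m),
        bounds=Bounds(0.0, 1.0),
        options={"time_limit": opts.time_limit, "mip_rel_gap": opts.mip_gap},
    )
    if res.x is None:
        # The empty selection is always feasible; reaching this branch means
        # the backend returned nothing (e.g. timeout before any incumbent).
        sel = Selection.empty(net)
        return ASNResult(sel, 0.0, "infeasible_guarded", [])

    x = np.round(res.x).astype(int)
    sel = Selection(
        {v: bool(x[node_idx[v]]) for v in nodes},
        {e.edge_id: bool(x[edge_idx[e.edge_id]]) for e in edges},
    )
    objective = subnetwork_score(scored, sel)
    status = "optimal" if res.status == 0 else "feasible_timeout"
    if abs(objective - (-res.fun)) > max(OBJECTIVE_ATOL, 1e-6 * abs(objective)):
        raise SolverFailure(
            f"solver objective {-res.fun} disagrees with recomputed {objective}"
        )
    return ASNResult(sel, objective, status, _components(scored, sel))


def brute_force_asn(scored: ScoredNetwork, max_edges: int = 20) -> ASNResult:
    """Exhaustive oracle: enumerate every feasible selection.

    Feasible selections correspond one-to-one to edge subsets (the node set
    is forced to be the endpoints of the chosen edges), so 2^|E| subsets
    cover the whole feasible region.  Intended for verification on tiny
    instances only.
    """
    net = scored.network
    edges = net.edges
    m = len(edges)
    if m > max_edges:
        raise ValueError(f"instance with {m} edges exceeds brute-force cap {max_edges}")

    node_coef = {v: scored.node_objective_coefficient(v) for v in net.nodes}
    edge_coef = [scored.edge_objective_coefficient(e.edge_id) for e in edges]

    best_score = 0.0
    best_mask = 0
    for mask in range(1 << m):
        score = 0.0
        seen: set[str] = set()
        for j in range(m):
            if mask >> j & 1:
                score += edge_coef[j]
                for v in edges[j].endpoints():
                    if v not in seen:
                        seen.add(v)
                        score += node_coef[v]
        if score > best_score:
            best_score, best_mask = score, mask

    chosen = {edges[j].edge_id for j in range(m) if best_mask >> j & 1}
    sel_nodes: set[str] = set()
    for j in range(m):
        if best_mask >> j & 1:
            sel_nodes.update(edges[j].endpoints())
    sel = Selection(
        {v: v in sel_nodes for v in net.nodes},
        {e.edge_id: e.edge_id in chosen for e in edges},
    )
    return ASNResult(sel, subnetwork_score(scored, sel), "optimal", _components(scored, sel))


def check_feasible(scored: ScoredNetwork, sel: Selection) -> bool:
    """True iff a selection satisfies coupling constraints (a)-(c)."""
    net = scored.network
    for e in net.edges:
        if sel.selected_edges[e.edge_id]:
            if not (sel.selected_nodes[e.source] and sel.selected_nodes[e.target]):
                return False
    for v in net.nodes:
        if sel.selected_nodes[v]:
            if not any(sel.selected_edges[e.edge_id] for e in net.incident_edges(v)):
                return False
    return True


def extract_components(result: ASNResult, scored: ScoredNetwork) -> list[set[str]]:
    """Connected components of the selected subgraph, best first.

    Direction is ignored; components are ordered by descending summed
    standardized node profit (ties broken by size then lexicographically).
    """
    return _components(scored, result.selection)


def _components(scored: ScoredNetwork, sel: Selection) -> list[set[str]]:
    import networkx as nx

    g = nx.Graph()
    g.add_nodes_from(sel.node_set())
    for e in scored.network.edges:
        if sel.selected_edges[e.edge_id]:
            g.add_edge(e.source, e.target)
    comps = [set(c) for c in nx.connected_components(g)]
    comps.sort(
        key=lambda c: (
            -sum(scored.node_profit_std[v] for v in c),
            -len(c),
            min(c),
        )
    )
    return comps
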