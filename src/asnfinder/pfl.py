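"""Positive feedback loop (PFL) enumeration on signed directed edges.

A PFL is a simple directed cycle built from activation/inhibition edges
whose product of edge signs (+ for activation, - for inhibition) is
positive, i.e. the cycle contains an even number of inhibitions.  Such
loops are the classic substrate of bistable switches in regulatory
networks.  Binding and ptm edges carry no sign and are excluded.

Enumeration is bounded simple-cycle search (Johnson-style, via networkx)
over the collapsed digraph of node pairs; parallel signed edges between the
same ordered pair expand into one loop per edge combination.  Cycles are
canonicalized by rotating the lexicographically smallest node to the front
(traversal order is fixed by edge direction, so no reflection is needed).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product
from typing import Iterable, Sequence

import networkx as nx

from .model import Edge, EdgeType, InteractionNetwork, SIGNED_EDGE_TYPES


@dataclass(frozen=True)
class FeedbackLoop:
    """A canonicalized simple directed cycle with its overall sign."""

    node_cycle: tuple[str, ...]
    edge_cycle: tuple[str, ...]
    sign: str  # "positive" | "negative"

    @property
    def length(self) -> int:
        return len(self.node_cycle)

    def edge_types(self, network: InteractionNetwork) -> tuple[str, ...]:
        return tuple(network.edge(eid).edge_type.value for eid in self.edge_cycle)


def _canonical_rotation(nodes: Sequence[str], edges: Sequence[str]) -> tuple[tuple[str, ...], tuple[str, ...]]:
    k = min(range(len(nodes)), key=lambda i: nodes[i])
    return tuple(nodes[k:]) + tuple(nodes[:k]), tuple(edges[k:]) + tuple(edges[:k])


def _loop_sign(edge_objs: Iterable[Edge]) -> str:
    inhibitions = sum(1 for e in edge_objs if e.edge_type is EdgeType.INHIBITION)
    return "positive" if inhibitions % 2 == 0 else "negative"


def find_pfls(
    network: InteractionNetwork,
    restrict_to: set[str] | None = None,
    max_length: int = 6,
    include_self_loops: bool = False,
) -> list[FeedbackLoop]:
    """All positive feedback loops of length <= ``max_length``.

    Parameters
    ----------
    network
        Mixed network; only activation/inhibition edges are traversed.
    restrict_to
        Optional node subset (e.g. a solved subnetwork); loops must lie
        entirely inside it.
    max_length
        Bound on cycle length; enumeration cost grows steeply beyond ~8.
    include_self_loops
        Count autoregulation (a length-1 activation cycle) as a PFL.

    Returns loops sorted by (length, node cycle) for reproducible output.
    """
    if max_length < 1:
        raise ValueError("max_length must be >= 1")
    allowed = network.nodes if restrict_to is None else set(restrict_to)

    # parallel signed edges per ordered pair
    arcs: dict[tuple[str, str], list[Edge]] = {}
    for e in network.edges:
        if e.edge_type not in SIGNED_EDGE_TYPES:
            continue
        if e.source not in allowed or e.target not in allowed:
            continue
        if e.source == e.target and not include_self_loops:
            continue
        arcs.setdefault((e.source, e.target), []).append(e)

    g = nx.DiGraph()
    g.add_edges_from(arcs.keys())

    loops: list[FeedbackLoop] = []
    for node_cycle in nx.simple_cycles(g, length_bound=max_length):
        pairs = [
            (node_cycle[i], node_cycle[(i + 1) % len(node_cycle)])
            for i in range(len(node_cycle))
        ]
        # every combination of parallel edges is a distinct loop
        for combo in product(*(arcs[p] for p in pairs)):
            if _loop_sign(combo) != "positive":
                continue
            nodes_c, edges_c = _canonical_rotation(
                node_cycle, [e.edge_id for e in combo]
            )
            loops.append(FeedbackLoop(nodes_c, edges_c, "positive"))
    loops.sort(key=lambda fl: (fl.length, fl.node_cycle, fl.edge_cycle))
    return loops


def pfl_conservation(
    pfls_a: list[FeedbackLoop],
    pfls_b: list[FeedbackLoop],
    network_a: InteractionNetwork,
    network_b: InteractionNetwork,
) -> list[FeedbackLoop]:
    """Loops present in both lists, matched by node cycle and edge types.

    Edge ids differ between networks, so identity is the canonical node
    cycle together with the sequence of edge types along it.
    """
    def key(fl: FeedbackLoop, net: InteractionNetwork) -> tuple:
        return (fl.node_cycle, fl.edge_types(net))

    keys_b = {key(fl, network_b) for fl in pfls_b}
    return [fl for fl in pfls_a if key(fl, network_a) in keys_b]


def write_pfls(
    pfls: list[FeedbackLoop], network: InteractionNetwork, path
) -> None:
    """One loop per row: ordered genes, edge types, length, sign."""
    from pathlib import Path

    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with path.open("w") as fh:
        fh.write("genes\tedge_types\tlength\tsign\n")
        for fl in pfls:
            fh.write(
                "{}\t{}\t{}\t{}\n".format(
                    ",".join(fl.node_cycle),
                    ",".join(fl.edge_types(network)),
                    fl.length,
                    fl.sign,
                )
            )
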