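"""Core domain types: typed interaction networks and expression tables.

The network model is a mixed multigraph G = (V, E).  Edges carry one of four
interaction types — physical binding (undirected), post-translational /
catalytic modification, activation, and inhibition (all directed
source → target) — and a confidence in (0, 1].  Two nodes may be joined by
several parallel edges of different types.

Expression data M = (V_exp, P, D) maps gene ids to a p-value and a direction
of regulation (up, down, or unchanged); a gene whose p-value exceeds the
significance threshold is always "unchanged".
"""

from __future__ import annotations

import math
import sys
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Iterator


class Direction(str, Enum):
    """Direction of differential regulation of a gene."""

    UP = "up"
    DOWN = "down"
    UNCHANGED = "unchanged"

    def flipped(self) -> "Direction":
        if self is Direction.UP:
            return Direction.DOWN
        if self is Direction.DOWN:
            return Direction.UP
        return Direction.UNCHANGED


class EdgeType(str, Enum):
    """Interaction type of an edge.  Only ``binding`` is undirected."""

    BINDING = "binding"
    PTM = "ptm"
    ACTIVATION = "activation"
    INHIBITION = "inhibition"


#: Edge types that carry a regulatory sign (used by the feedback-loop finder).
SIGNED_EDGE_TYPES = frozenset({EdgeType.ACTIVATION, EdgeType.INHIBITION})

#: Smallest p-value substituted for an exact zero (log p must be finite).
MIN_P_VALUE = sys.float_info.min


@dataclass(frozen=True)
class Edge:
    """A typed, confidence-weighted interaction between two genes."""

    edge_id: str
    source: str
    target: str
    edge_type: EdgeType
    confidence: float

    def __post_init__(self) -> None:
        if not 0.0 < self.confidence <= 1.0:
            raise ValueError(
                f"edge {self.edge_id!r}: confidence {self.confidence} outside (0, 1]"
            )

    @property
    def directed(self) -> bool:
        return self.edge_type is not EdgeType.BINDING

    def endpoints(self) -> tuple[str, str]:
        return (self.source, self.target)


@dataclass(frozen=True)
class ExpressionRecord:
    """Per-gene differential-expression result: p-value plus direction."""

    gene_id: str
    p_value: float
    direction: Direction

    def __post_init__(self) -> None:
        if not 0.0 < self.p_value <= 1.0:
            raise ValueError(
                f"gene {self.gene_id!r}: p-value {self.p_value} outside (0, 1]"
            )


class ExpressionData:
    """Mapping of gene id to :class:`ExpressionRecord` with a p-value cutoff.

    ``significance_threshold`` is the p-value above which a gene's direction
    is forced to ``unchanged``; records are normalized on construction.
    """

    def __init__(
        self,
        records: Iterable[ExpressionRecord],
        significance_threshold: float = 0.05,
    ) -> None:
        if not 0.0 < significance_threshold < 1.0:
            raise ValueError(f"significance threshold {significance_threshold} outside (0, 1)")
        self.significance_threshold = significance_threshold
        self.records: dict[str, ExpressionRecord] = {}
        for rec in records:
            if rec.gene_id in self.records:
                raise ValueError(f"duplicate gene id {rec.gene_id!r}")
            if rec.p_value > significance_threshold and rec.direction is not Direction.UNCHANGED:
                rec = ExpressionRecord(rec.gene_id, rec.p_value, Direction.UNCHANGED)
            self.records[rec.gene_id] = rec

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self.records

    def __len__(self) -> int:
        return len(self.records)

    def direction_of(self, gene_id: str) -> Direction:
        """Direction of a gene; ``unchanged`` for genes absent from the table."""
        rec = self.records.get(gene_id)
        return rec.direction if rec is not None else Direction.UNCHANGED

    def p_value_of(self, gene_id: str) -> float | None:
        rec = self.records.get(gene_id)
        return rec.p_value if rec is not None else None


class InteractionNetwork:
    """A mixed multigraph of typed interactions.

    Maintains an index from edge id to edge and an incidence index from node
    to the edges touching it (in either orientation).  Every edge endpoint
    must be a declared node; isolated nodes are allowed.
    """

    def __init__(self, nodes: Iterable[str], edges: Iterable[Edge]) -> None:
        self.nodes: set[str] = set(nodes)
        self.edges: list[Edge] = []
        self._by_id: dict[str, Edge] = {}
        self._incident: dict[str, list[Edge]] = {n: [] for n in self.nodes}
        for e in edges:
            self.add_edge(e)

    def add_edge(self, e: Edge) -> None:
        if e.edge_id in self._by_id:
            raise ValueError(f"duplicate edge id {e.edge_id!r}")
        for endpoint in e.endpoints():
            if endpoint not in self.nodes:
                raise ValueError(
                    f"edge {e.edge_id!r} endpoint {endpoint!r} is not a declared node"
                )
        self.edges.append(e)
        self._by_id[e.edge_id] = e
        self._incident[e.source].append(e)
        if e.target != e.source:
            self._incident[e.target].append(e)

    def edge(self, edge_id: str) -> Edge:
        return self._by_id[edge_id]

    def incident_edges(self, node: str) -> list[Edge]:
        return self._incident[node]

    def neighbors(self, node: str) -> set[str]:
        """Distinct neighbors of a node, ignoring direction and parallel edges."""
        out: set[str] = set()
        for e in self._incident[node]:
            out.add(e.target if e.source == node else e.source)
        out.discard(node)
        return out

    def degree(self, node: str) -> int:
        """Number of distinct neighbors (parallel edges counted once)."""
        return len(self.neighbors(node))

    def __iter__(self) -> Iterator[Edge]:
        return iter(self.edges)

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def subnetwork(self, node_subset: Iterable[str], edge_ids: Iterable[str]) -> "InteractionNetwork":
        """Induced subnetwork over explicit node and edge subsets."""
        keep = set(edge_ids)
        return InteractionNetwork(
            set(node_subset), [e for e in self.edges if e.edge_id in keep]
        )


def clamp_p_value(p: float) -> float:
    """Replace a p-value of exactly 0 with the smallest positive float.

    Node scores take log(p), so zero p-values (common after aggressive
    rounding in DE tables) must be nudged off zero rather than rejected.
    """
    if p == 0.0:
        return MIN_P_VALUE
    if math.isnan(p):
        raise ValueError("p-value is NaN")
    return p
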