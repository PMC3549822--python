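"""Readers and writers for the file dialects the tool touches.

Network input is a tab-separated edge list.  Two dialects are supported:

``native``
    Header row, columns ``source  target  type  confidence[  note]`` with
    type in {binding, ptm, activation, inhibition} and confidence in (0, 1].
    When the fifth column is headed ``edge_id`` its values are used as
    stable edge identifiers (written by :func:`write_network`, so that
    simulated gold-standard edge sets can be matched after a round trip);
    otherwise ids are generated positionally.

``string_actions``
    STRING "actions"-style export with mode/action vocabulary and integer
    combined scores 0-1000.  Modes map onto the native types (activation →
    activation, inhibition → inhibition, binding → binding,
    ptmod/catalysis → ptm); unmapped modes are skipped with a warning and
    scores are rescaled to (0, 1] by dividing by 1000.

Expression input is a TSV of gene id, p-value, and either a signed
direction column (+1/-1) or a signed log-fold-change; the sign is used only
for genes at or below the significance threshold.

A solved subnetwork is written as a SIF edge file plus node/edge attribute
TSVs and a JSON summary, the layout Cytoscape-era tools expect.
"""

from __future__ import annotations

import csv
import json
import logging
import math
from pathlib import Path
from typing import TYPE_CHECKING

from .model import (
    Direction,
    Edge,
    EdgeType,
    ExpressionData,
    ExpressionRecord,
    InteractionNetwork,
    clamp_p_value,
)

if TYPE_CHECKING:  # pragma: no cover
    from .scoring import ScoredNetwork, Selection
    from .solver import ASNResult

logger = logging.getLogger(__name__)

_NATIVE_TYPES = {t.value: t for t in EdgeType}

# Best-effort mapping of STRING action modes onto the four native types.
_STRING_MODE_MAP = {
    "activation": EdgeType.ACTIVATION,
    "inhibition": EdgeType.INHIBITION,
    "binding": EdgeType.BINDING,
    "ptmod": EdgeType.PTM,
    "catalysis": EdgeType.PTM,
}


class NetworkLoadError(ValueError):
    """Raised when a network file fails validation; message names the line."""


class ExpressionLoadError(ValueError):
    """Raised when an expression table fails validation."""


def read_network(path: str | Path, dialect: str = "native") -> InteractionNetwork:
    """Load an interaction network from a TSV edge list.

    Parameters
    ----------
    path
        Tab-separated file; first row is a header and is skipped.
    dialect
        ``"native"`` or ``"string_actions"`` (see module docstring).
    """
    if dialect not in ("native", "string_actions"):
        raise ValueError(f"unknown network dialect {dialect!r}")
    path = Path(path)
    nodes: set[str] = set()
    edges: list[Edge] = []
    ids_in_col5 = False
    with path.open() as fh:
        reader = csv.reader(fh, delimiter="\t")
        for lineno, row in enumerate(reader, start=1):
            if lineno == 1:
                ids_in_col5 = (
                    dialect == "native" and len(row) >= 5 and row[4].strip() == "edge_id"
                )
                continue
            if not row or row[0].startswith("#"):
                continue
            if len(row) < 4:
                raise NetworkLoadError(f"{path}:{lineno}: expected >= 4 columns, got {len(row)}")
            source, target, type_token, conf_token = (c.strip() for c in row[:4])
            if dialect == "native":
                edge_type = _NATIVE_TYPES.get(type_token)
                if edge_type is None:
                    raise NetworkLoadError(
                        f"{path}:{lineno}: unknown edge type {type_token!r}"
                    )
                confidence = _parse_float(conf_token, path, lineno, "confidence")
            else:
                edge_type = _STRING_MODE_MAP.get(type_token)
                if edge_type is None:
                    logger.warning(
                        "%s:%d: skipping unmapped STRING mode %r", path, lineno, type_token
                    )
                    continue
                raw = _parse_float(conf_token, path, lineno, "score")
                confidence = raw / 1000.0
            if not 0.0 < confidence <= 1.0:
                raise NetworkLoadError(
                    f"{path}:{lineno}: confidence {confidence} outside (0, 1]"
                )
            nodes.update((source, target))
            if ids_in_col5 and len(row) >= 5 and row[4].strip():
                edge_id = row[4].strip()
            else:
                edge_id = f"e{len(edges) + 1:06d}"
            edges.append(Edge(edge_id, source, target, edge_type, confidence))
    try:
        return InteractionNetwork(nodes, edges)
    except ValueError as exc:
        raise NetworkLoadError(f"{path}: {exc}") from exc


def _parse_float(token: str, path: Path, lineno: int, what: str) -> float:
    try:
        return float(token)
    except ValueError as exc:
        raise NetworkLoadError(f"{path}:{lineno}: bad {what} {token!r}") from exc


def read_expression(path: str | Path, significance_threshold: float = 0.05) -> ExpressionData:
    """Load a differential-expression table.

    Columns (tab-separated, header skipped): gene id, p-value, signed
    direction (+1/-1) or signed log-fold-change.  The direction becomes
    up/down from the sign only when p <= ``significance_threshold``;
    otherwise the gene is recorded as unchanged.  Zero p-values are clamped
    to the smallest positive float with a warning.
    """
    path = Path(path)
    records: list[ExpressionRecord] = []
    seen: set[str] = set()
    with path.open() as fh:
        reader = csv.reader(fh, delimiter="\t")
        for lineno, row in enumerate(reader, start=1):
            if lineno == 1 or not row or row[0].startswith("#"):
                continue
            if len(row) < 3:
                raise ExpressionLoadError(
                    f"{path}:{lineno}: expected 3 columns (gene, p, sign)"
                )
            gene = row[0].strip()
            if gene in seen:
                raise ExpressionLoadError(f"{path}:{lineno}: duplicate gene id {gene!r}")
            seen.add(gene)
            try:
                p = float(row[1])
                sign = float(row[2])
            except ValueError as exc:
                raise ExpressionLoadError(f"{path}:{lineno}: bad numeric field") from exc
            if p == 0.0:
                logger.warning("%s:%d: p-value 0 clamped to smallest positive float", path, lineno)
                p = clamp_p_value(p)
            if not 0.0 < p <= 1.0 or math.isnan(p):
                raise ExpressionLoadError(
                    f"{path}:{lineno}: p-value {row[1]} outside (0, 1]"
                )
            if p <= significance_threshold and sign != 0.0:
                direction = Direction.UP if sign > 0 else Direction.DOWN
            else:
                direction = Direction.UNCHANGED
            records.append(ExpressionRecord(gene, p, direction))
    return ExpressionData(records, significance_threshold)


def write_asn(result: "ASNResult", scored: "ScoredNetwork", prefix: str | Path) -> dict[str, Path]:
    """Write a solved subnetwork to ``<prefix>.sif`` and companion tables.

    Emits four files: a SIF of the selected edges, a node attribute TSV
    (p-value, direction, raw and standardized scores, selected flag), an
    edge attribute TSV (type, confidence, consistency score, selected flag),
    and a JSON summary with the objective value and component list.
    Returns the mapping of artifact name to path.
    """
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    net = scored.network
    sel = result.selection

    sif_path = prefix.with_suffix(".sif")
    with sif_path.open("w") as fh:
        for e in net.edges:
            if sel.selected_edges[e.edge_id]:
                fh.write(f"{e.source}\t{e.edge_type.value}\t{e.target}\n")

    nodes_path = prefix.parent / (prefix.name + ".nodes.tsv")
    with nodes_path.open("w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(
            ["gene", "p_value", "direction", "profit", "profit_std", "cost", "cost_std", "selected"]
        )
        for n in sorted(net.nodes):
            p = scored.expression.p_value_of(n)
            w.writerow(
                [
                    n,
                    "" if p is None else f"{p:.6g}",
                    scored.expression.direction_of(n).value,
                    f"{scored.node_profit[n]:.6g}",
                    f"{scored.node_profit_std[n]:.6g}",
                    f"{scored.node_cost[n]:.6g}",
                    f"{scored.node_cost_std[n]:.6g}",
                    int(sel.selected_nodes[n]),
                ]
            )

    edges_path = prefix.parent / (prefix.name + ".edges.tsv")
    with edges_path.open("w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(
            ["edge_id", "source", "target", "type", "confidence", "consistency", "score", "score_std", "selected"]
        )
        for e in net.edges:
            w.writerow(
                [
                    e.edge_id,
                    e.source,
                    e.target,
                    e.edge_type.value,
                    f"{e.confidence:.6g}",
                    f"{scored.edge_consistency[e.edge_id]:.6g}",
                    f"{scored.edge_score[e.edge_id]:.6g}",
                    f"{scored.edge_score_std[e.edge_id]:.6g}",
                    int(sel.selected_edges[e.edge_id]),
                ]
            )

    summary_path = prefix.parent / (prefix.name + ".summary.json")
    summary = {
        "objective": result.objective,
        "status": result.status,
        "n_selected_nodes": sum(sel.selected_nodes.values()),
        "n_selected_edges": sum(sel.selected_edges.values()),
        "components": [sorted(c) for c in result.components],
    }
    summary_path.write_text(json.dumps(summary, indent=2, sort_keys=True) + "\n")

    return {"sif": sif_path, "nodes": nodes_path, "edges": edges_path, "summary": summary_path}


def read_asn_nodes(nodes_path: str | Path) -> set[str]:
    """Selected node set from a node attribute TSV written by :func:`write_asn`."""
    selected: set[str] = set()
    with Path(nodes_path).open() as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        for row in reader:
            if int(row["selected"]):
                selected.add(row["gene"])
    return selected


def read_asn_edges(edges_path: str | Path) -> set[str]:
    """Selected edge-id set from an edge attribute TSV written by :func:`write_asn`."""
    selected: set[str] = set()
    with Path(edges_path).open() as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        for row in reader:
            if int(row["selected"]):
                selected.add(row["edge_id"])
    return selected


def write_network(network: InteractionNetwork, path: str | Path) -> None:
    """Write a network in the native TSV dialect (round-trips with read_network)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with path.open("w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["source", "target", "type", "confidence", "edge_id"])
        for e in network.edges:
            w.writerow(
                [e.source, e.target, e.edge_type.value, f"{e.confidence:.6g}", e.edge_id]
            )


def write_expression(expr: ExpressionData, path: str | Path) -> None:
    """Write an expression table in the native TSV dialect."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    sign = {Direction.UP: 1, Direction.DOWN: -1, Direction.UNCHANGED: 0}
    with path.open("w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["gene", "p_value", "direction"])
        for gene in sorted(expr.records):
            rec = expr.records[gene]
            w.writerow([gene, repr(rec.p_value), sign[rec.direction]])
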