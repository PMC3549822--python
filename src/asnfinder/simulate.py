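"""Simulated benchmark instances with planted gold-standard subnetworks.

Each instance has N nodes of which a fixed fraction (default 0.1) are
"significant": their p-values are drawn uniformly below a cutoff (default
0.001) while all other nodes get uniform p-values above it.  Each
significant node is assigned an up/down direction with equal probability.
For every replicate, 2n random ordered pairs of significant nodes (n the
number of significant nodes, multiplier configurable) receive a directed
edge whose type — activation for same-direction endpoints, inhibition for
opposite — is consistent with that replicate's directions, all with a
constant confidence (default 1).  Replicates after the first redraw every
p-value within the same significant/non-significant partition and flip the
directions of a fixed fraction (default 0.5) of significant nodes, so the
same node pair can acquire differently-typed edges across replicates, as in
real curated networks.  The returned network is the union multigraph over
replicates; the planted nodes and per-replicate edge sets are the gold
standard for precision/recall evaluation.

Counts are exact (round(fraction * n), sampling without replacement), not
Bernoulli draws, so the design fractions hold for every seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict, field
from pathlib import Path

import numpy as np

from .model import (
    Direction,
    Edge,
    EdgeType,
    ExpressionData,
    ExpressionRecord,
    InteractionNetwork,
)


@dataclass(frozen=True)
class SimulationConfig:
    """Benchmark design constants.

    n_nodes : network size N (the benchmark uses 100, 1000, 10000).
    sig_fraction : fraction of nodes planted as significant (0.1).
    sig_p_max : p-value ceiling of significant nodes (0.001).
    edge_multiplier : planted edges per significant node (2).
    confidence_value : constant confidence of planted edges (1.0).
    flip_fraction : fraction of significant nodes whose direction flips in
        each replicate after the first (0.5).
    n_replicates : number of expression replicates (10, 15 or 20).
    significance_threshold : p-value cutoff stored with each replicate's
        expression table (analysis-side, not a generator quantity).
    """

    n_nodes: int = 100
    sig_fraction: float = 0.1
    sig_p_max: float = 0.001
    edge_multiplier: int = 2
    confidence_value: float = 1.0
    flip_fraction: float = 0.5
    n_replicates: int = 10
    seed: int = 0
    significance_threshold: float = 0.05

    def __post_init__(self) -> None:
        if self.n_nodes < 2:
            raise ValueError("n_nodes must be >= 2")
        if not 0.0 < self.sig_fraction < 1.0:
            raise ValueError(f"sig_fraction {self.sig_fraction} outside (0, 1)")
        if not 0.0 <= self.flip_fraction <= 1.0:
            raise ValueError(f"flip_fraction {self.flip_fraction} outside [0, 1]")
        if not 0.0 < self.sig_p_max < 1.0:
            raise ValueError(f"sig_p_max {self.sig_p_max} outside (0, 1)")
        if self.edge_multiplier < 1 or self.n_replicates < 1:
            raise ValueError("edge_multiplier and n_replicates must be >= 1")
        if not 0.0 < self.confidence_value <= 1.0:
            raise ValueError(f"confidence_value {self.confidence_value} outside (0, 1]")

    @property
    def n_significant(self) -> int:
        return round(self.sig_fraction * self.n_nodes)

    @property
    def n_gold_edges(self) -> int:
        return self.edge_multiplier * self.n_significant

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class SimulatedInstance:
    """Generated network, expression replicates and the planted gold standard."""

    config: SimulationConfig
    network: InteractionNetwork
    replicates: list[ExpressionData]
    gold_nodes: set[str]
    gold_edges_per_replicate: list[set[str]]


def _node_name(i: int, width: int) -> str:
    return f"g{i:0{width}d}"


def generate_instance(config: SimulationConfig) -> SimulatedInstance:
    """Generate one benchmark instance; deterministic given ``config.seed``."""
    rng = np.random.default_rng(config.seed)
    N = config.n_nodes
    n_sig = config.n_significant
    n_edges = config.n_gold_edges
    if n_edges > n_sig * (n_sig - 1):
        raise ValueError(
            f"{n_edges} gold edges exceed the {n_sig * (n_sig - 1)} distinct "
            "ordered significant-node pairs available"
        )

    width = len(str(N - 1))
    node_names = [_node_name(i, width) for i in range(N)]
    sig_idx = np.sort(rng.choice(N, size=n_sig, replace=False))
    sig_names = [node_names[i] for i in sig_idx]
    gold_nodes = set(sig_names)
    is_sig = np.zeros(N, dtype=bool)
    is_sig[sig_idx] = True

    # replicate-1 directions of the significant nodes
    base_up = rng.random(n_sig) < 0.5
    n_flip = round(config.flip_fraction * n_sig)

    replicates: list[ExpressionData] = []
    all_edges: list[Edge] = []
    gold_edges_per_replicate: list[set[str]] = []
    for r in range(config.n_replicates):
        # fresh p-values each replicate, same significant partition
        p = np.empty(N)
        p[is_sig] = rng.uniform(0.0, config.sig_p_max, size=n_sig)
        p[~is_sig] = rng.uniform(config.sig_p_max, 1.0, size=N - n_sig)
        np.maximum(p, np.finfo(float).tiny, out=p)

        up = base_up.copy()
        if r > 0 and n_flip > 0:
            flip = rng.choice(n_sig, size=n_flip, replace=False)
            up[flip] = ~up[flip]
        direction_of = {
            name: (Direction.UP if u else Direction.DOWN)
            for name, u in zip(sig_names, up)
        }

        records = []
        for i, name in enumerate(node_names):
            d = direction_of.get(name, Direction.UNCHANGED)
            records.append(ExpressionRecord(name, float(p[i]), d))
        replicates.append(ExpressionData(records, config.significance_threshold))

        # distinct ordered pairs of significant nodes
        pair_codes = rng.choice(n_sig * (n_sig - 1), size=n_edges, replace=False)
        edge_ids: set[str] = set()
        for k, code in enumerate(pair_codes):
            i, j = divmod(int(code), n_sig - 1)
            if j >= i:
                j += 1
            src, tgt = sig_names[i], sig_names[j]
            etype = EdgeType.ACTIVATION if up[i] == up[j] else EdgeType.INHIBITION
            eid = f"r{r + 1}_e{k + 1:04d}"
            all_edges.append(Edge(eid, src, tgt, etype, config.confidence_value))
            edge_ids.add(eid)
        gold_edges_per_replicate.append(edge_ids)

    network = InteractionNetwork(node_names, all_edges)
    return SimulatedInstance(
        config, network, replicates, gold_nodes, gold_edges_per_replicate
    )


def write_instance(instance: SimulatedInstance, out_dir: str | Path) -> dict[str, Path]:
    """Write an instance bundle: network TSV, per-replicate expression TSVs,
    and a gold-standard JSON (nodes, per-replicate edge ids, config echo).

    Output is byte-identical for identical configs (sorted keys, no
    timestamps)."""
    from .io import write_expression, write_network

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    net_path = out_dir / "network.tsv"
    write_network(instance.network, net_path)
    paths["network"] = net_path

    for r, expr in enumerate(instance.replicates, start=1):
        p = out_dir / f"expression_r{r}.tsv"
        write_expression(expr, p)
        paths[f"expression_r{r}"] = p

    gold = {
        "config": instance.config.to_dict(),
        "gold_nodes": sorted(instance.gold_nodes),
        "gold_edges_per_replicate": [
            sorted(s) for s in instance.gold_edges_per_replicate
        ],
    }
    gold_path = out_dir / "gold_standard.json"
    gold_path.write_text(json.dumps(gold, indent=2, sort_keys=True) + "\n")
    paths["gold"] = gold_path
    return paths
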