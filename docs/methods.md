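# Methods

## Model and assumptions

The input is (i) a mixed multigraph of interactions — activation,
inhibition and ptm edges directed source → target, binding edges
undirected, each with a confidence in (0, 1], parallel edges of different
types allowed — and (ii) a per-gene differential-expression table of
p-values and directions.  The method assumes gene identifiers match
exactly between the two inputs (no alias resolution), that p-values are
comparable across genes, and that an edge's biological sign is adequately
captured by its curated type.  A gene whose p-value exceeds the
significance threshold is treated as unchanged regardless of its fold
change sign; a network gene absent from the expression table scores a
fixed penalty (default 1.0) and direction unchanged.

## Scores

* Node profit `W_n = (a − 1)(log p − log τ)`, natural log.  `a` is the
  shape parameter of a beta-uniform mixture view of the p-value
  distribution; it only rescales profits uniformly (standardization removes
  the effect), so it is a user input with default 0 rather than a fitted
  quantity.  `τ` (default 0.05) is the significance level at which profit
  changes sign and is the main knob controlling subnetwork size.
* Node cost `C_n = log D` with `D` the number of *distinct* neighbors;
  parallel edges do not inflate the cost, and isolated nodes get cost 0 by
  convention (log 0 undefined; such nodes can never be selected anyway).
* Edge consistency: activation +2/−1/−2 for same/unchanged/opposite
  endpoint directions; inhibition +2 for opposite, −2 for same, −1
  otherwise.  The inhibition case with *both* endpoints unchanged is not
  distinguished from the one-endpoint-unchanged case: both take the mild
  −1 penalty, the least-inconsistent reading of an uninformative edge.
  Binding and ptm edges take a constant weight, default −1 (use +1 to favor
  PPI-style edges).  Edge score `S_e = W_e · C_e` (confidence scaling).
* Standardization divides each class (profits, costs, edge scores) by its
  maximum absolute value, so each standardized score lies in [−1, 1] and
  at least one attains magnitude 1; an all-zero class standardizes to all
  zeros (guarded division).  Standardization makes the objective invariant
  to uniform rescaling of any score class — in particular to the log base,
  which is why fixing natural logs is a presentation choice, not a modeling
  one (it does fix the scale of the raw scores written to output tables).

## Objective and integer program

`S = Σ_n x_n (α W′_n − β_n C′_n) + γ Σ_e x_e S′_e`, maximized over boolean
`x`.  β is applied per node: `beta_positive` (default 0) when the
standardized profit is ≥ 0, `beta_negative` (default 1) otherwise, so
strongly significant hubs are not squeezed out while insignificant hubs pay
full connectivity cost.  α = γ = 1 by default.  Constraints: a selected
node needs at least one selected incident edge (incidence counted in
either orientation — requiring an *outgoing* edge would forbid terminal
targets); a selected edge needs both endpoints.  Consequently the empty
selection is feasible and the optimum is never negative, and the selected
node set is exactly the endpoint set of the selected edges — which the
brute-force oracle exploits by enumerating edge subsets only.

Connectedness is *not* a constraint; the solver reports the connected
components of the selection ordered by summed standardized profit, and the
CLI's `--top-component` flag restricts the output to the best one.

The backend is HiGHS through `scipy.optimize.milp`.  The reported
objective is always recomputed from the returned selection by an
independent evaluation of the objective (tolerance 1e-6 against the
solver's value); ties between optimal selections are broken arbitrarily by
the backend, so tests compare objectives, not selections.  `nca_mode`
(node-centric ablation) scores every edge as undirected with consistency
+1, removing all direction/type information.

## Positive feedback loops

A PFL is a simple directed cycle over activation/inhibition edges whose
product of signs (+ activation, − inhibition) is positive, i.e. with an
even number of inhibitions — the standard systems-biology definition.
Binding/ptm edges are excluded (no sign).  Enumeration is bounded
Johnson-style simple-cycle search (networkx `simple_cycles` with
`length_bound`, default 6 — enumeration is exponential and reported
biological loops rarely exceed this) on the collapsed digraph, followed by
expansion over parallel signed edges: each combination of parallel edges
along a node cycle is a distinct loop.  Cycles are canonicalized by
rotating the lexicographically smallest node to the front; traversal order
is fixed by edge direction so no reflection is needed.  Self-loops count
as length-1 PFLs only when requested (default off).  Conservation between
two loop sets matches the canonical node cycle together with the edge-type
sequence, since edge ids are network-specific.

## Benchmark generator

Each instance plants round(0.1 · N) significant nodes among N (defaults
N = 100; the design supports 100/1000/10000) with p-values uniform on
(0, 0.001), all others uniform on (0.001, 1), and assigns each significant
node up/down with probability ½.  Per replicate, 2 · n distinct *ordered*
pairs of significant nodes receive a directed edge typed to be consistent
with that replicate's directions (activation for same-direction pairs,
inhibition for opposite), all with confidence 1.  Replicates after the
first redraw every p-value within the fixed significant/non-significant
partition and flip the directions of exactly round(0.5 · n) significant
nodes, so the union multigraph can hold differently-typed edges between
the same pair, as real curated networks do.  Counts are exact
(round + sampling without replacement), not Bernoulli, so the design
fractions are testable identities.  Determinism: one `numpy` Generator
seeded from the config drives every draw, and bundles are written with
sorted keys and no timestamps, so equal configs give byte-identical files.

What the simulation does *not* emulate: background network structure
(non-significant nodes are isolated, so there is no hub/connectivity
confound and no decoy edges), correlated p-values, binding/ptm edges, and
measurement error in edge confidences.  Recovery results on it therefore
demonstrate correctness of scoring + optimization, not performance on real
networks.  One consequence of edge sampling: a planted node that happens
to receive no edge in a replicate is unrecoverable by construction (the
coupling constraints forbid isolated selections); with 2n edges over n
nodes this affects a given node with probability ≈ 0.8^{2n}·…≈ 1%.

## Evaluation

Node and edge precision (TP / predicted-positive) and recall
(TP / gold-positive), edges matched by id (ids persist through the native
TSV round trip via a dedicated `edge_id` column).  Degenerate 0/0 ratios
report 1.0 — an empty prediction claims nothing falsely, an empty gold
standard is fully recovered — while recall against a nonempty gold with no
hits is 0.  Per-replicate metrics are reported individually plus their
arithmetic mean.

## Numerical and design choices

* p-values of exactly 0 are clamped to the smallest positive double with a
  warning (log p must be finite); NaN is rejected.
* The simplified significant-list score is implemented as
  `W_n = −log p` (positive for significant genes), i.e. Eq. form at a = 0,
  τ = 1; a sign convention making list scores negative would contradict
  the profit interpretation.
* STRING actions mapping: activation → activation, inhibition → inhibition,
  binding → binding, ptmod/catalysis → ptm; other modes are skipped with a
  logged warning; integer scores are divided by 1000.
* Solver options: time limit (default 300 s) and relative MIP gap
  (default 0, i.e. proven optimality); hitting the limit returns the
  incumbent with status `feasible_timeout`.
* Test problem sizes: oracle cross-checks use ≤ 8 nodes / ≤ 12 edges
  (exhaustive enumeration is exact there), recovery tests use N = 100–200,
  and generator measurements use N = 1000 — large enough that the design
  fractions are informative, small enough to keep the suite in seconds.

## Limitations

Exact MIP solving scales to the few-thousand-node subnetworks typical of
query-driven analyses, not to whole interactomes with dense hub regions;
the time limit then yields a feasible, not certified-optimal, selection.
The consistency scheme reads each edge independently — it cannot model
combinatorial regulation (AND/OR logic) or sign changes through ptm
cascades.  PFL enumeration is exponential in the length bound.  The
per-class standardization couples every score to the single most extreme
node/edge, so one outlier p-value compresses all other profits.
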