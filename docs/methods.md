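# Methods

## Scope and data model

The toolkit operates on three in-memory containers:

* `InteractionGraph` — an undirected protein–protein interaction graph
  (networkx-backed). Nodes carry a stable `node_id`, optional NCBI-style
  integer gene id, symbol, UniProt-style protein accession, a single
  cellular-location string, and three annotation sets (function,
  phenotype, pathway). Edges are stored canonically (endpoints sorted),
  duplicates are merged and their provenance tags unioned, so node and
  edge counts always describe deduplicated collections.
* `DiseaseGeneTable` / `PathwayDefinition` — disease–gene association
  records, and pathways as member sets (each member classed as signal,
  protein or gene) with six typed, signed interaction lists.
* `BooleanNetwork` — ordered nodes 1..N with either one logic-expression
  rule per node (parsed AST) or one signed regulator list per node, plus
  a clamp map and a self-degrading set. A node is never both clamped and
  self-degrading; clamping removes a node from the self-degrading set.

Input formats are plain TSV (column layout given by an explicit `Dialect`
config, never sniffed, so runs are bit-reproducible), YAML pathway
documents, and rule files in the `$node[i] = expr;` syntax. Outputs are
Cytoscape SIF (+ TSV node-attribute sidecar), edge-list text, ranked
crosstalk text, SBML XML, and a transition-table text format.

## PPI neighborhoods

`expand_neighborhood(seed, k)` returns the subgraph *induced* on the ball
of shortest-path radius k around the seed — including edges between two
nodes at the same distance. This is the standard reading of counts like
"n proteins possessing m edges" for a neighborhood, and it is the
definition all fixture counts in the tests are computed under. Whether a
given curated platform includes same-level edges in its own counts is
generally not documented, so the choice is stated here rather than
asserted as universal. Per-level reports carry both cumulative
(distance ≤ k) and incremental (distance = k) node counts because both
styles appear in practice. Self-loops are excluded from expansion by
default (biological PPI sets rarely carry them); a flag re-includes them.
The degree cap defaults to 3 and is overridable.

Identifier resolution order is: exact node_id, then numeric gene id, then
symbol (case-insensitive), then protein accession; an ambiguous symbol is
an error that lists the candidates rather than guessing.

## Disease projection and pathway crosstalk

The disease–disease edge rule is genuinely underdetermined in the
literature (shared genes vs interacting gene products), so both modes are
implemented; `shared` is the default and the chosen mode is recorded in
the output header. Shared-mode weight is the size of the gene-set
intersection, hence bounded by the smaller gene set and symmetric; the
interacting mode counts unordered cross pairs (g1, g2), g1 ≠ g2, with a
PPI edge between them.

Crosstalk between two pathways is counted on shared node identifiers
(after the same resolution as the PPI queries); a secondary column counts
shared typed, signed interactions, since shared-edge counting is the other
plausible definition. Ranking is by shared-member count descending, ties
broken by pathway name, which makes the output order total and stable.

The six interaction classes are labeled with their endpoints ordered
signal < protein < gene (there is a Sig-Gene class but no Gene-Sig); the
interaction itself remains directed and signed, the class label is just
its unordered type.

## SBML export

Each pathway member becomes one species; each interaction becomes one
irreversible reaction. With only "first-order rates" to go on, the two
rate-law templates were chosen so that the exported model is immediately
simulatable mass action without auxiliary species:

* activation X → Y: synthesis of Y with X as modifier, rate k·[X];
* inhibition X ⊣ Y: degradation of Y with X as modifier, rate k·[X]·[Y].

Both templates are overridable. Every rate constant is a reaction-local
parameter initialized to `k_default` (default 1.0 — a placeholder, flagged
as unparameterized by an annotation element) and species start at amount
1.0 unless configured otherwise. The dialect is SBML Level 2 Version 4,
the era most widely supported by CellDesigner-class tools. Output is
byte-deterministic: member ids are sorted, reactions follow the pathway's
interaction order, and SId sanitization (non-alphanumerics to `_`,
deterministic collision suffixes) depends only on the input. A structural
validator (unique ids, resolvable compartment/species references, every
kinetic-law symbol declared in its reaction) runs in the tests and in the
CLI before writing.

## Boolean engine

States are integers whose zero-padded binary rendering lists node 1
leftmost, so the string "0100010100" reads node1=0, node2=1, … and
string lexicographic order coincides with numeric order.

Two synchronous update semantics are implemented, reflecting the two
common ways regulatory logic is specified:

* **logic mode** — per-node NOT/AND/OR expressions, evaluated on the
  current global state for all nodes simultaneously;
* **threshold mode** — per-node signed regulator lists; node i switches
  on iff Σ_j a_ij·S_j(t) ≥ 1 (activation +1, inhibition −1). The
  threshold is sharp: a sum of 0 or less gives 0; there is no stochastic
  tie-breaking. A node with no regulators holds its state — which
  reproduces constant-input behavior such as a growth-factor node defined
  as its own identity — unless it is flagged self-degrading, in which
  case it decays to 0.

Clamped nodes keep their clamp value regardless of their rule; edge
counts (literal occurrences in logic mode, regulator entries in threshold
mode) always describe the parsed rule set, not the perturbation.
Asynchronous updating is an explicit non-goal.

Attractor analysis enumerates all 2^N successors (the enumeration cap
defaults to 20 nodes ≈ 10^6 states and must be raised explicitly beyond
that) and finds the cycles of the successor function by iterative orbit
following with path compression: each state's orbit is walked until it
hits a labeled state or closes a new cycle, then the whole walked path is
labeled. Each cycle is reported once in canonical rotation (starting at
its numerically smallest state) so attractor sets compare exactly across
implementations; basin sizes include the cycle's own states and always
sum to 2^N. The engine contains no randomness. The test suite checks it
against an intentionally naive independent oracle that restarts explicit
cycle detection from every single state.

The rule grammar is parsed by a hand-written tokenizer and recursive
descent parser (precedence NOT > AND > OR, `#` comments, whitespace
insensitive) that reports line/column on syntax errors; N is the number
of statements, each of nodes 1..N must be defined exactly once, and any
literal index outside 1..N is a structural error. "Edges" of a logic-mode
network are counted as literal occurrences on rule right-hand sides —
this is the definition under which the bundled cell-cycle rule set has
49 edges, and it is the documented meaning throughout.

## Bundled fixtures and generators

The bundled interactome fixture is intentionally minimal: the
A2M–APOE–APP chain and angiogenin with its seven first-neighbor proteins
and their functional groupings — just the facts exercised by the worked
examples, with no attempt to mimic a real interactome snapshot (second-
and third-neighborhood counts of a curated database depend on that
database's contents and are out of scope; neighborhood correctness is
instead property-tested against a hand-rolled BFS oracle on generated
graphs). The cell-cycle rule file ships verbatim as data.

The random generators (interactomes, Boolean networks, disease tables,
pathway catalogs) are pure functions of their arguments; randomness comes
from Python's `random.Random` (Mersenne Twister) seeded per call, so
repeated calls agree bit for bit. Generated Boolean networks draw 1..max
in-degree distinct regulators per node and either a random NOT/AND/OR
expression over them or random signs. Synthetic data is labeled as such
(evidence tags, docstrings); the PSEN1-style pathway used in the SBML
tests is a synthetic stand-in wiring diagram, not curated biology.

## Problem sizes and numerical choices

Exhaustive checks run at sizes where exact oracles are cheap: attractor
cross-validation uses 100 random networks with N ≤ 4 (256 orbit starts
each at most), basin-partition properties go up to N = 8, projection and
crosstalk oracles use tables of ~6 diseases × 40 genes and catalogs of
~10 pathways over 30 symbols. The full acceptance recomputation finishes
in well under a second; the bundled 10-node model's 1024-state
enumeration is instantaneous.

## Known limitations

* Exhaustive enumeration is exponential in N; no SAT/BDD-based attractor
  detection for large networks.
* One location string per node; conflicting locations from merged sources
  are kept first-wins and surfaced as warnings.
* SBML validation is structural, not a full consistency check against the
  SBML specification schema.
* The fixtures demonstrate correctness of the algorithms, not properties
  of any real curated interactome; passing tests say nothing about the
  coverage or quality of real association data.
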