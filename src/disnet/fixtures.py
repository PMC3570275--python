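"""Bundled worked-example data and deterministic random generators.

The bundled fixtures carry only the handful of interactions and annotations
used in the worked examples (the A2M/APOE/APP triangle query and the
angiogenin first neighborhood); they are not a snapshot of any real
interactome.  The random generators are pure functions of their arguments —
the seed fully determines the output (Python's Mersenne Twister via
``random.Random``) — so tests and cross-checks are bit-reproducible.
"""

from __future__ import annotations

import random
from importlib import resources

from .dynamics import BooleanNetwork, parse_rules
from .errors import ConfigurationError
from .graph import Dialect, InteractionGraph, attach_annotations, read_annotations, read_edge_table
from .projections import SPECIES_CLASSES, DiseaseGeneTable, PathwayDefinition

#: Node labels of the bundled cell-cycle network, in node order 1..10.
CELL_CYCLE_LABELS = [
    "CycD", "Rb", "E2F", "CycE", "CycA", "p27", "CDC20", "CDH1", "UbcH10", "CycB",
]

#: Column mapping of the bundled toy PPI edge table.
TOY_DIALECT = Dialect(a="a", b="b", provenance="source",
                      location_a="location_a", location_b="location_b", header=True)


def _data_path(name: str):
    return resources.files("disnet.data").joinpath(name)


def cellcycle_rules() -> str:
    """The ten mammalian cell-cycle rule statements, as rule-file text."""
    return _data_path("cellcycle.bool").read_text(encoding="utf-8")


def cellcycle_network() -> BooleanNetwork:
    """The parsed 10-node cell-cycle network with product labels attached."""
    return parse_rules(cellcycle_rules(), labels=list(CELL_CYCLE_LABELS))


def toy_interactome() -> InteractionGraph:
    """Toy PPI graph: the A2M/APOE/APP chain plus angiogenin and its seven
    first neighbors, annotated with the worked-example functional groupings."""
    with resources.as_file(_data_path("toy_ppi.tsv")) as p:
        graph = read_edge_table(p, TOY_DIALECT)
    with resources.as_file(_data_path("toy_annotations.tsv")) as p:
        attach_annotations(graph, read_annotations(p))
    return graph


# ---------------------------------------------------------------------------
# seeded random generators


def random_interactome(n: int, m: int, seed: int) -> InteractionGraph:
    """Random simple undirected graph with exactly n nodes and m edges."""
    if n < 1 or m < 0:
        raise ConfigurationError("need n >= 1 and m >= 0")
    if m > n * (n - 1) // 2:
        raise ConfigurationError(f"m={m} exceeds the {n * (n - 1) // 2} possible pairs")
    rng = random.Random(seed)
    width = len(str(n))
    ids = [f"N{i:0{width}d}" for i in range(1, n + 1)]
    graph = InteractionGraph()
    for nid in ids:
        graph.ensure_node(nid)
    pairs: set[tuple[str, str]] = set()
    while len(pairs) < m:
        a, b = rng.sample(ids, 2)
        pairs.add((min(a, b), max(a, b)))
    for a, b in sorted(pairs):
        graph.add_edge(a, b, ("random",))
    return graph


def _random_expr(regs: list[int], rng: random.Random):
    """Random NOT/AND/OR expression whose literals are exactly ``regs``."""
    def leaf(j: int):
        lit = ("lit", j)
        return ("not", lit) if rng.random() < 0.5 else lit

    expr = leaf(regs[0])
    for j in regs[1:]:
        op = rng.choice(("and", "or"))
        expr = (op, expr, leaf(j))
    return expr


def random_boolean_network(
    n: int, max_in_degree: int, mode: str = "logic", seed: int = 0
) -> BooleanNetwork:
    """Random Boolean network; per node, 1..max_in_degree distinct regulators
    combined into a random logic expression, or given random signs
    (threshold mode)."""
    if n < 1 or max_in_degree < 1:
        raise ConfigurationError("need n >= 1 and max_in_degree >= 1")
    if mode not in ("logic", "threshold"):
        raise ConfigurationError(f"unknown mode {mode!r}")
    rng = random.Random(seed)
    cap = min(max_in_degree, n)
    if mode == "logic":
        rules = {}
        for i in range(1, n + 1):
            regs = sorted(rng.sample(range(1, n + 1), rng.randint(1, cap)))
            rules[i] = _random_expr(regs, rng)
        return BooleanNetwork(n=n, rules=rules)
    regulators = {}
    for i in range(1, n + 1):
        regs = sorted(rng.sample(range(1, n + 1), rng.randint(1, cap)))
        regulators[i] = [(j, rng.choice((1, -1))) for j in regs]
    return BooleanNetwork(n=n, regulators=regulators)


def random_disease_table(d: int, g: int, seed: int) -> DiseaseGeneTable:
    """Random disease-gene table: d diseases over a pool of g genes, each
    disease drawing between 1 and max(1, g//2) distinct genes."""
    if d < 1 or g < 1:
        raise ConfigurationError("need d >= 1 and g >= 1")
    rng = random.Random(seed)
    genes = [f"G{i:03d}" for i in range(1, g + 1)]
    table = DiseaseGeneTable()
    for k in range(1, d + 1):
        size = rng.randint(1, max(1, g // 2))
        for gene in sorted(rng.sample(genes, size)):
            table.add(f"D{k:02d}", gene, evidence="synthetic")
    return table


def random_pathways(p: int, universe: int, seed: int) -> list[PathwayDefinition]:
    """p random pathways over a shared universe of molecular symbols, with
    typed, signed interactions among each pathway's members."""
    if p < 1 or universe < 2:
        raise ConfigurationError("need p >= 1 and universe >= 2")
    rng = random.Random(seed)
    symbols = [f"M{i:03d}" for i in range(1, universe + 1)]
    classes = {s: rng.choice(SPECIES_CLASSES) for s in symbols}
    pathways = []
    for k in range(1, p + 1):
        size = rng.randint(2, min(8, universe))
        members = sorted(rng.sample(symbols, size))
        pw = PathwayDefinition(name=f"PW{k:02d}", members={m: classes[m] for m in members})
        n_edges = rng.randint(1, 2 * size)
        seen = set()
        for _ in range(n_edges):
            a, b = rng.sample(members, 2)
            sign = rng.choice(("activation", "inhibition"))
            if (a, b, sign) in seen:
                continue
            seen.add((a, b, sign))
            pw.add_interaction(a, b, sign)
        pathways.append(pw)
    return pathways
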