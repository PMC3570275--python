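"""PPI subnetwork induction, k-hop neighborhood expansion, and annotation filters.

Neighborhood semantics: ``expand_neighborhood`` returns the subgraph *induced*
on the ball of shortest-path radius k around the seed, i.e. it includes edges
between two nodes at the same distance.  Per-level counts are reported both
cumulatively (distance <= k) and incrementally (distance == k), matching the
two reporting styles used when describing growing neighborhoods.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import networkx as nx

from .errors import AmbiguousIdentifier, ConfigurationError, DisnetError, LookupFailure
from .graph import ANNOTATION_CATEGORIES, InteractionGraph

#: Default upper limit on the neighborhood degree.
DEFAULT_DEGREE_CAP = 3


def resolve_identifier(graph: InteractionGraph, identifier: str) -> str:
    """Map a user-supplied identifier to a node_id.

    Resolution order: exact node_id, then gene_id, then symbol
    (case-insensitive), then protein_id.  A symbol shared by several nodes
    raises :class:`AmbiguousIdentifier` listing the candidates.
    """
    if identifier in graph:
        return identifier
    ident = identifier.strip()
    if ident.isdigit():
        gid = int(ident)
        hits = [n.node_id for n in graph.nodes() if n.gene_id == gid]
        if len(hits) == 1:
            return hits[0]
        if len(hits) > 1:
            raise AmbiguousIdentifier(identifier, hits)
    low = ident.lower()
    hits = [n.node_id for n in graph.nodes() if n.symbol and n.symbol.lower() == low]
    if len(hits) == 1:
        return hits[0]
    if len(hits) > 1:
        raise AmbiguousIdentifier(identifier, hits)
    hits = [n.node_id for n in graph.nodes() if n.protein_id == ident]
    if len(hits) == 1:
        return hits[0]
    if len(hits) > 1:
        raise AmbiguousIdentifier(identifier, hits)
    raise LookupFailure(f"identifier {identifier!r} not found in graph")


def resolve_many(graph: InteractionGraph, identifiers: list[str]) -> tuple[list[str], list[str]]:
    """Resolve a list; returns (resolved node_ids, unresolved inputs)."""
    resolved, missing = [], []
    for ident in identifiers:
        try:
            resolved.append(resolve_identifier(graph, ident))
        except AmbiguousIdentifier:
            raise
        except LookupFailure:
            missing.append(ident)
    return resolved, missing


def induce_subnetwork(genes: list[str], graph: InteractionGraph) -> InteractionGraph:
    """Subgraph induced on the query set: only edges with both endpoints queried.

    Unresolvable entries are reported as warnings, not errors; an empty query
    yields an empty graph with a warning.
    """
    if not genes:
        warnings.warn("empty query list: returning empty graph", stacklevel=2)
        return InteractionGraph()
    resolved, missing = resolve_many(graph, genes)
    if missing:
        warnings.warn(f"unresolved identifiers ignored: {', '.join(missing)}", stacklevel=2)
    return graph.subgraph(resolved)


@dataclass(frozen=True)
class LevelCount:
    """Node/edge tally for one neighborhood level."""

    k: int
    nodes_cumulative: int   # nodes at distance <= k (seed included)
    nodes_new: int          # nodes at distance == k
    edges_cumulative: int   # edges of the induced subgraph on the <=k ball


@dataclass
class Neighborhood:
    """Result of a k-hop expansion: the induced subgraph plus per-level counts."""

    seed: str
    k: int
    graph: InteractionGraph
    levels: list[LevelCount]


def expand_neighborhood(
    seed: str,
    k: int,
    graph: InteractionGraph,
    degree_cap: int = DEFAULT_DEGREE_CAP,
    include_self_loops: bool = False,
) -> Neighborhood:
    """Induced subgraph on all nodes within shortest-path distance k of ``seed``.

    ``k`` must lie in 1..``degree_cap`` (default 3).  Self-loops on the seed
    or its neighbors are dropped unless ``include_self_loops`` is set.
    """
    if not 1 <= k <= degree_cap:
        raise ConfigurationError(f"neighborhood degree {k} out of range 1..{degree_cap}")
    seed_id = resolve_identifier(graph, seed)
    g = graph.nx_graph()
    if not include_self_loops:
        g = nx.restricted_view(g, [], [(n, n) for n in g.nodes if g.has_edge(n, n)])
    dist = nx.single_source_shortest_path_length(g, seed_id, cutoff=k)
    levels: list[LevelCount] = []
    for level in range(1, k + 1):
        ball = [n for n, d in dist.items() if d <= level]
        new = sum(1 for d in dist.values() if d == level)
        sub = graph.subgraph(ball)
        n_edges = sub.n_edges
        if not include_self_loops:
            n_edges -= sum(1 for a, b in sub.edges() if a == b)
        levels.append(LevelCount(level, len(ball), new, n_edges))
    result_graph = graph.subgraph(list(dist))
    if not include_self_loops:
        for a, b in [e for e in result_graph.edges() if e[0] == e[1]]:
            result_graph.nx_graph().remove_edge(a, b)
    return Neighborhood(seed=seed_id, k=k, graph=result_graph, levels=levels)


def filter_network(
    graph: InteractionGraph,
    category: str,
    term: str | None = None,
):
    """Filter or group a network by annotation.

    With ``term``: returns the induced :class:`InteractionGraph` on nodes
    carrying that term in ``category``.  Without ``term``: returns a dict
    term -> set of node_ids (a node may fall in several groups).
    """
    if category not in ANNOTATION_CATEGORIES:
        raise ConfigurationError(
            f"unknown category {category!r}; expected one of {ANNOTATION_CATEGORIES}"
        )
    if term is not None:
        keep = [n.node_id for n in graph.nodes() if term in n.annotations(category)]
        return graph.subgraph(keep)
    groups: dict[str, set[str]] = {}
    for node in graph.nodes():
        for t in node.annotations(category):
            groups.setdefault(t, set()).add(node.node_id)
    return groups


def format_level_report(nb: Neighborhood) -> str:
    """Human-readable per-level summary, TSV-ish, one line per level."""
    lines = ["degree\tnodes_cumulative\tnodes_new\tedges_cumulative"]
    for lv in nb.levels:
        lines.append(f"{lv.k}\t{lv.nodes_cumulative}\t{lv.nodes_new}\t{lv.edges_cumulative}")
    return "\n".join(lines) + "\n"
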