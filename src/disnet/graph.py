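"""Molecular interaction graphs: data model, TSV readers, and SIF output.

The central container is :class:`InteractionGraph`, an undirected graph of
:class:`MolecularNode` records backed by :mod:`networkx`.  Edges are stored
canonically (endpoint ids sorted), duplicates are merged, and each edge
carries a set of provenance tags naming the sources that reported it.

File formats
------------
* Edge tables: tab-separated text, column layout described by a
  :class:`Dialect` (config-driven, never sniffed).  Lines starting with
  ``#`` are comments.  Encoding is UTF-8.
* Annotation tables: ``node_id <TAB> category <TAB> term`` with category in
  ``{function, phenotype, pathway}``.
* Output: Cytoscape SIF (``node <TAB> type <TAB> node``) plus a TSV node
  attribute sidecar carrying gene and protein identifiers.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping

import networkx as nx

from .errors import ConfigurationError, InputError

ANNOTATION_CATEGORIES = ("function", "phenotype", "pathway")

#: SIF interaction type used for protein-protein edges.
PPI_SIF_TYPE = "pp"


@dataclass
class MolecularNode:
    """A gene/protein node with cross-database identifiers and annotations.

    At least one of ``gene_id`` (NCBI-Gene-style integer), ``symbol`` or
    ``protein_id`` (UniProt-style accession) must be present; ``node_id``
    is the stable key used throughout the toolkit.
    """

    node_id: str
    gene_id: int | None = None
    symbol: str | None = None
    protein_id: str | None = None
    location: str | None = None
    functions: set[str] = field(default_factory=set)
    phenotypes: set[str] = field(default_factory=set)
    pathways: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        if self.gene_id is None and self.symbol is None and self.protein_id is None:
            # a bare node_id created from an edge file doubles as its symbol
            self.symbol = self.node_id

    def annotations(self, category: str) -> set[str]:
        if category == "function":
            return self.functions
        if category == "phenotype":
            return self.phenotypes
        if category == "pathway":
            return self.pathways
        raise ConfigurationError(
            f"unknown annotation category {category!r}; expected one of {ANNOTATION_CATEGORIES}"
        )


class InteractionGraph:
    """Undirected, deduplicated interaction graph over :class:`MolecularNode`."""

    def __init__(self) -> None:
        self._g = nx.Graph()

    # -- construction -------------------------------------------------

    def add_node(self, node: MolecularNode) -> MolecularNode:
        """Insert ``node``; merging annotation sets if the id already exists."""
        existing = self.get_node(node.node_id)
        if existing is None:
            self._g.add_node(node.node_id, data=node)
            return node
        for attr in ("gene_id", "symbol", "protein_id"):
            if getattr(existing, attr) is None and getattr(node, attr) is not None:
                setattr(existing, attr, getattr(node, attr))
        if node.location is not None:
            if existing.location is not None and existing.location != node.location:
                warnings.warn(
                    f"conflicting locations for {node.node_id}: "
                    f"keeping {existing.location!r}, ignoring {node.location!r}",
                    stacklevel=2,
                )
            else:
                existing.location = node.location
        existing.functions |= node.functions
        existing.phenotypes |= node.phenotypes
        existing.pathways |= node.pathways
        return existing

    def ensure_node(self, node_id: str) -> MolecularNode:
        node = self.get_node(node_id)
        if node is None:
            node = MolecularNode(node_id=node_id)
            self._g.add_node(node_id, data=node)
        return node

    def add_edge(self, a: str, b: str, provenance: Iterable[str] = ()) -> None:
        """Add undirected edge a-b, creating missing endpoints; merges provenance."""
        self.ensure_node(a)
        self.ensure_node(b)
        tags = set(provenance)
        if self._g.has_edge(a, b):
            self._g.edges[a, b]["provenance"] |= tags
        else:
            self._g.add_edge(a, b, provenance=tags)

    # -- queries ------------------------------------------------------

    def get_node(self, node_id: str) -> MolecularNode | None:
        if node_id in self._g:
            return self._g.nodes[node_id]["data"]
        return None

    def __contains__(self, node_id: str) -> bool:
        return node_id in self._g

    def has_edge(self, a: str, b: str) -> bool:
        return self._g.has_edge(a, b)

    def provenance(self, a: str, b: str) -> set[str]:
        return self._g.edges[a, b]["provenance"]

    def neighbors(self, node_id: str) -> set[str]:
        return set(self._g.neighbors(node_id))

    @property
    def node_ids(self) -> set[str]:
        return set(self._g.nodes)

    def nodes(self) -> Iterator[MolecularNode]:
        for nid in self._g.nodes:
            yield self._g.nodes[nid]["data"]

    def edges(self) -> Iterator[tuple[str, str]]:
        """Canonical (a <= b) endpoint pairs."""
        for a, b in self._g.edges:
            yield (a, b) if a <= b else (b, a)

    @property
    def n_nodes(self) -> int:
        return self._g.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self._g.number_of_edges()

    def nx_graph(self) -> nx.Graph:
        """The underlying networkx graph (shared, not a copy)."""
        return self._g

    # -- derived graphs ------------------------------------------------

    def subgraph(self, node_ids: Iterable[str]) -> "InteractionGraph":
        """Induced subgraph on ``node_ids`` (unknown ids ignored)."""
        keep = {n for n in node_ids if n in self._g}
        out = InteractionGraph()
        for nid in keep:
            out.add_node(self._g.nodes[nid]["data"])
        for a, b in self._g.edges:
            if a in keep and b in keep:
                out.add_edge(a, b, self._g.edges[a, b]["provenance"])
        return out

    def equals(self, other: "InteractionGraph") -> bool:
        """Equality on node-id sets and canonical edge sets."""
        return self.node_ids == other.node_ids and set(self.edges()) == set(other.edges())


@dataclass(frozen=True)
class Dialect:
    """Column mapping for tab-separated edge tables.

    Columns are addressed by header name (``header=True``) or by zero-based
    index.  Only ``a`` and ``b`` are required; ``provenance``, ``location_a``
    and ``location_b`` are optional extras.
    """

    a: str | int = 0
    b: str | int = 1
    provenance: str | int | None = None
    location_a: str | int | None = None
    location_b: str | int | None = None
    header: bool = False

    def _index(self, key: str | int | None, header_row: list[str] | None, path: str) -> int | None:
        if key is None:
            return None
        if isinstance(key, int):
            return key
        if header_row is None:
            raise ConfigurationError(
                f"dialect maps column by name {key!r} but header=False ({path})"
            )
        try:
            return header_row.index(key)
        except ValueError:
            raise ConfigurationError(
                f"mapped column {key!r} not found in header of {path}; "
                f"header columns: {header_row}"
            ) from None


def _data_lines(path: str | Path) -> Iterator[tuple[int, list[str]]]:
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n").rstrip("\r")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            yield lineno, line.split("\t")


def read_edge_table(path: str | Path, dialect: Dialect = Dialect()) -> InteractionGraph:
    """Load a TSV edge table into a deduplicated undirected graph.

    Unknown identifiers become nodes carrying only that identifier.  An empty
    file yields an empty graph.  A missing mapped column raises
    :class:`ConfigurationError` naming the column.
    """
    graph = InteractionGraph()
    rows = _data_lines(path)
    header_row: list[str] | None = None
    if dialect.header:
        try:
            _, header_row = next(rows)
        except StopIteration:
            return graph
    spath = str(path)
    ia = dialect._index(dialect.a, header_row, spath)
    ib = dialect._index(dialect.b, header_row, spath)
    iprov = dialect._index(dialect.provenance, header_row, spath)
    iloca = dialect._index(dialect.location_a, header_row, spath)
    ilocb = dialect._index(dialect.location_b, header_row, spath)
    for lineno, cells in rows:
        if len(cells) <= max(ia, ib):
            raise InputError(
                f"expected at least {max(ia, ib) + 1} columns, found {len(cells)}",
                path=spath,
                line=lineno,
            )
        a, b = cells[ia].strip(), cells[ib].strip()
        if not a or not b:
            raise InputError("empty identifier field", path=spath, line=lineno)
        prov: tuple[str, ...] = ()
        if iprov is not None and iprov < len(cells) and cells[iprov].strip():
            prov = tuple(t.strip() for t in cells[iprov].split(",") if t.strip())
        graph.add_edge(a, b, prov)
        if iloca is not None and iloca < len(cells) and cells[iloca].strip():
            graph.get_node(a).location = graph.get_node(a).location or cells[iloca].strip()
        if ilocb is not None and ilocb < len(cells) and cells[ilocb].strip():
            graph.get_node(b).location = graph.get_node(b).location or cells[ilocb].strip()
    return graph


def read_annotations(path: str | Path) -> dict[str, dict[str, set[str]]]:
    """Read ``node_id / category / term`` rows into per-node annotation sets.

    Every returned mapping has all three categories present (possibly empty).
    An unknown category raises :class:`InputError` citing the line number.
    """
    out: dict[str, dict[str, set[str]]] = {}
    for lineno, cells in _data_lines(path):
        if len(cells) < 3:
            raise InputError("expected 3 columns (node_id, category, term)", str(path), lineno)
        node_id, category, term = (c.strip() for c in cells[:3])
        if category not in ANNOTATION_CATEGORIES:
            raise InputError(
                f"unknown annotation category {category!r}; "
                f"expected one of {ANNOTATION_CATEGORIES}",
                str(path),
                lineno,
            )
        slot = out.setdefault(node_id, {c: set() for c in ANNOTATION_CATEGORIES})
        slot[category].add(term)
    return out


def attach_annotations(graph: InteractionGraph, annotations: Mapping[str, Mapping[str, set[str]]]) -> None:
    """Merge an annotation mapping into the graph's nodes (unknown ids ignored)."""
    for node_id, cats in annotations.items():
        node = graph.get_node(node_id)
        if node is None:
            continue
        node.functions |= cats.get("function", set())
        node.phenotypes |= cats.get("phenotype", set())
        node.pathways |= cats.get("pathway", set())


def write_sif(
    graph: InteractionGraph,
    path: str | Path,
    attrs_path: str | Path | None = None,
    interaction_type: str = PPI_SIF_TYPE,
) -> None:
    """Write Cytoscape SIF plus a TSV node-attribute sidecar.

    Edges appear one per line in stable lexicographic order; the sidecar
    (default ``<path>.nodes.tsv``) lists node_id, symbol, gene_id, protein_id
    and location so external tools can map to global identifiers.  An empty
    graph yields an empty SIF file.
    """
    path = Path(path)
    lines = [f"{a}\t{interaction_type}\t{b}" for a, b in sorted(graph.edges())]
    path.write_text("".join(line + "\n" for line in lines), encoding="utf-8")
    if attrs_path is None:
        attrs_path = path.with_name(path.name + ".nodes.tsv")
    rows = ["node_id\tsymbol\tgene_id\tprotein_id\tlocation"]
    for node in sorted(graph.nodes(), key=lambda n: n.node_id):
        rows.append(
            "\t".join(
                str(v) if v is not None else ""
                for v in (node.node_id, node.symbol, node.gene_id, node.protein_id, node.location)
            )
        )
    Path(attrs_path).write_text("".join(r + "\n" for r in rows), encoding="utf-8")


#: Dialect for reading SIF files back (a <TAB> type <TAB> b).
SIF_DIALECT = Dialect(a=0, b=2)
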