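"""Disease-disease projections and pathway crosstalk.

``disease_projection`` builds a weighted disease-disease graph from a
disease-gene association table.  Two edge rules are provided because both
readings are common in the disease-network literature:

* ``shared`` (default): diseases are linked iff they share at least one
  associated gene; the weight is the number of shared genes.
* ``interacting``: diseases are linked iff some gene product of one has a
  PPI edge to some gene product of the other; the weight is the number of
  such cross pairs (shared genes are not double counted as self-pairs).

``pathway_crosstalk`` ranks catalog pathways by the number of molecular
components shared with a query pathway; a secondary column counts shared
(typed, signed) interactions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import networkx as nx
import yaml

from .errors import ConfigurationError, InputError
from .graph import InteractionGraph, _data_lines

SPECIES_CLASSES = ("signal", "protein", "gene")
_CLASS_TAG = {"signal": "Sig", "protein": "Prot", "gene": "Gene"}
#: The six typed interaction classes, directed (source class - target class).
EDGE_CLASSES = ("Sig-Sig", "Sig-Prot", "Sig-Gene", "Prot-Prot", "Prot-Gene", "Gene-Gene")
SIGNS = ("activation", "inhibition")


def _edge_class(class_a: str, class_b: str) -> str:
    """Canonical typed class for an interaction between two species classes.

    The class label orders its endpoints signal < protein < gene (there is a
    Sig-Gene class but no Gene-Sig); the interaction itself stays directed.
    """
    ia, ib = SPECIES_CLASSES.index(class_a), SPECIES_CLASSES.index(class_b)
    first, second = (class_a, class_b) if ia <= ib else (class_b, class_a)
    return f"{_CLASS_TAG[first]}-{_CLASS_TAG[second]}"


# ---------------------------------------------------------------------------
# disease-gene associations


@dataclass
class DiseaseGeneTable:
    """Unique (disease, gene) association records with evidence tags."""

    records: list[tuple[str, str, str]] = field(default_factory=list)

    def add(self, disease: str, gene: str, evidence: str = "") -> None:
        if any(d == disease and g == gene for d, g, _ in self.records):
            return
        self.records.append((disease, gene, evidence))

    def genes_by_disease(self) -> dict[str, set[str]]:
        out: dict[str, set[str]] = {}
        for disease, gene, _ in self.records:
            out.setdefault(disease, set()).add(gene)
        return out

    @property
    def diseases(self) -> list[str]:
        return sorted(self.genes_by_disease())

    @classmethod
    def from_tsv(cls, path: str | Path) -> "DiseaseGeneTable":
        """Read ``disease <TAB> gene [<TAB> evidence]`` rows."""
        table = cls()
        for lineno, cells in _data_lines(path):
            if len(cells) < 2:
                raise InputError("expected >= 2 columns (disease, gene)", str(path), lineno)
            disease, gene = cells[0].strip(), cells[1].strip()
            if not disease or not gene:
                raise InputError("empty disease or gene field", str(path), lineno)
            evidence = cells[2].strip() if len(cells) > 2 else ""
            table.add(disease, gene, evidence)
        return table


def disease_projection(
    table: DiseaseGeneTable,
    mode: str = "shared",
    ppi: InteractionGraph | None = None,
) -> nx.Graph:
    """Project a disease-gene table onto a weighted disease-disease graph."""
    if mode not in ("shared", "interacting"):
        raise ConfigurationError(f"unknown projection mode {mode!r}")
    if mode == "interacting" and ppi is None:
        raise ConfigurationError("mode 'interacting' requires a PPI graph")
    by_disease = table.genes_by_disease()
    if not by_disease:
        raise InputError("disease-gene table is empty")
    diseases = sorted(by_disease)
    g = nx.Graph(mode=mode)
    g.add_nodes_from(diseases)
    for i, d1 in enumerate(diseases):
        for d2 in diseases[i + 1:]:
            if mode == "shared":
                weight = len(by_disease[d1] & by_disease[d2])
            else:
                weight = sum(
                    1
                    for ga in by_disease[d1]
                    for gb in by_disease[d2]
                    if ga != gb and ga in ppi and gb in ppi and ppi.has_edge(ga, gb)
                )
            if weight > 0:
                g.add_edge(d1, d2, weight=weight)
    return g


def write_projection(g: nx.Graph, path: str | Path) -> None:
    """Edge-list text output; the header records the projection mode."""
    lines = [f"# disease projection, mode={g.graph.get('mode', 'shared')}"]
    for d1, d2 in sorted(g.edges()):
        lines.append(f"{d1}\t{d2}\t{g.edges[d1, d2]['weight']}")
    Path(path).write_text("".join(x + "\n" for x in lines), encoding="utf-8")


# ---------------------------------------------------------------------------
# pathways


@dataclass(frozen=True)
class TypedEdge:
    """One signed interaction inside a pathway definition."""

    a: str
    b: str
    edge_class: str  # one of EDGE_CLASSES
    sign: str        # activation | inhibition


@dataclass
class PathwayDefinition:
    """A pathway as a node set with six typed, signed interaction lists."""

    name: str
    members: dict[str, str]          # node_id -> species class
    interactions: list[TypedEdge] = field(default_factory=list)
    locations: dict[str, str] = field(default_factory=dict)  # node_id -> cellular location

    def __post_init__(self) -> None:
        for node, cls in self.members.items():
            if cls not in SPECIES_CLASSES:
                raise InputError(
                    f"pathway {self.name!r}: member {node!r} has unknown class {cls!r}"
                )
        for e in self.interactions:
            self._check_edge(e)

    def _check_edge(self, e: TypedEdge) -> None:
        for endpoint in (e.a, e.b):
            if endpoint not in self.members:
                raise InputError(
                    f"pathway {self.name!r}: interaction endpoint {endpoint!r} is not a member"
                )
        if e.sign not in SIGNS:
            raise InputError(f"pathway {self.name!r}: unknown sign {e.sign!r}")
        expected = _edge_class(self.members[e.a], self.members[e.b])
        if e.edge_class not in EDGE_CLASSES:
            raise InputError(f"pathway {self.name!r}: unknown edge class {e.edge_class!r}")
        if e.edge_class != expected:
            raise InputError(
                f"pathway {self.name!r}: edge {e.a}->{e.b} declared {e.edge_class} "
                f"but endpoint classes imply {expected}"
            )

    def add_interaction(self, a: str, b: str, sign: str) -> TypedEdge:
        """Add an interaction, deriving the typed class from member classes."""
        edge = TypedEdge(a, b, _edge_class(self.members[a], self.members[b]), sign)
        self._check_edge(edge)
        self.interactions.append(edge)
        return edge

    def member_set(self) -> set[str]:
        return set(self.members)

    def interaction_set(self) -> set[TypedEdge]:
        return set(self.interactions)

    # -- YAML round-trip ------------------------------------------------

    def to_yaml(self) -> str:
        doc = {
            "name": self.name,
            "members": [
                {"id": nid, "class": cls, **({"location": self.locations[nid]} if nid in self.locations else {})}
                for nid, cls in sorted(self.members.items())
            ],
            "interactions": [
                {"a": e.a, "b": e.b, "class": e.edge_class, "sign": e.sign}
                for e in self.interactions
            ],
        }
        return yaml.safe_dump(doc, sort_keys=False)

    @classmethod
    def from_yaml(cls, text: str) -> "PathwayDefinition":
        doc = yaml.safe_load(text)
        if not isinstance(doc, dict) or "name" not in doc or "members" not in doc:
            raise InputError("pathway document must define 'name' and 'members'")
        members = {m["id"]: m["class"] for m in doc["members"]}
        locations = {m["id"]: m["location"] for m in doc["members"] if "location" in m}
        interactions = [
            TypedEdge(e["a"], e["b"], e["class"], e["sign"])
            for e in doc.get("interactions", [])
        ]
        return cls(name=doc["name"], members=members, interactions=interactions, locations=locations)

    @classmethod
    def from_file(cls, path: str | Path) -> "PathwayDefinition":
        return cls.from_yaml(Path(path).read_text(encoding="utf-8"))


@dataclass(frozen=True)
class CrosstalkRecord:
    """One pathway sharing components with the query."""

    pathway: str
    shared_count: int
    shared_members: tuple[str, ...]
    shared_edge_count: int


def pathway_crosstalk(
    query: PathwayDefinition,
    catalog: Iterable[PathwayDefinition],
) -> list[CrosstalkRecord]:
    """Rank catalog pathways by shared components with ``query``.

    Sorted by shared-member count descending, then name.  The query itself
    (matched by name) is excluded; duplicate catalog names are an input error.
    """
    catalog = list(catalog)
    names = [p.name for p in catalog]
    if len(names) != len(set(names)):
        dupes = sorted({n for n in names if names.count(n) > 1})
        raise InputError(f"duplicate pathway names in catalog: {', '.join(dupes)}")
    qmembers = query.member_set()
    qedges = query.interaction_set()
    records = []
    for p in catalog:
        if p.name == query.name:
            continue
        shared = qmembers & p.member_set()
        if not shared:
            continue
        shared_edges = len(qedges & p.interaction_set())
        records.append(
            CrosstalkRecord(p.name, len(shared), tuple(sorted(shared)), shared_edges)
        )
    records.sort(key=lambda r: (-r.shared_count, r.pathway))
    return records


def write_crosstalk(records: list[CrosstalkRecord], query_name: str, path: str | Path) -> None:
    lines = [
        f"# pathway crosstalk with {query_name}",
        "pathway\tshared_members\tshared_edges\tmembers",
    ]
    for r in records:
        lines.append(
            f"{r.pathway}\t{r.shared_count}\t{r.shared_edge_count}\t{','.join(r.shared_members)}"
        )
    Path(path).write_text("".join(x + "\n" for x in lines), encoding="utf-8")
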