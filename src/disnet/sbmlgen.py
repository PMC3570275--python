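"""SBML (Level 2 Version 4) export of signal-gene-protein pathways.

Every pathway member becomes a species; every signed interaction becomes a
reaction with first-order mass-action kinetics:

* activation X -> Y: a synthesis reaction producing Y with X as modifier,
  rate ``k*[X]``;
* inhibition X -| Y: a degradation reaction consuming Y with X as modifier,
  rate ``k*[X]*[Y]``.

Both templates can be swapped via the ``templates`` mapping.  All rate
constants are local parameters initialized to ``k_default`` and flagged with
an annotation marking them as unparameterized placeholders, to be replaced
when kinetic data is available.  Output is byte-deterministic for identical
input: member ids are sorted, reactions follow the pathway's interaction
order, and id sanitization is stable.
"""

from __future__ import annotations

import re
from typing import Mapping

from lxml import etree

from .errors import ConfigurationError, InputError
from .projections import PathwayDefinition

SBML_NS = "http://www.sbml.org/sbml/level2/version4"
MATHML_NS = "http://www.w3.org/1998/Math/MathML"
ANNOT_NS = "urn:disnet:sbml-export"

DEFAULT_COMPARTMENT = "cell"

#: sign -> reaction template; "synthesis" produces the target, "degradation"
#: consumes it (and includes the target in the rate law).
DEFAULT_TEMPLATES: Mapping[str, str] = {"activation": "synthesis", "inhibition": "degradation"}

_ID_OK = re.compile(r"[^A-Za-z0-9_]")


def _sanitize_ids(names: list[str]) -> dict[str, str]:
    """Deterministic member-name -> SBML SId map (collision-suffixed)."""
    mapping: dict[str, str] = {}
    used: set[str] = set()
    for name in sorted(names):
        sid = _ID_OK.sub("_", name)
        if not sid or sid[0].isdigit():
            sid = "s_" + sid
        base = sid
        k = 2
        while sid in used:
            sid = f"{base}_{k}"
            k += 1
        used.add(sid)
        mapping[name] = sid
    return mapping


def _math_times(cis: list[str]) -> etree._Element:
    math = etree.Element(f"{{{MATHML_NS}}}math")
    apply_ = etree.SubElement(math, f"{{{MATHML_NS}}}apply")
    etree.SubElement(apply_, f"{{{MATHML_NS}}}times")
    for name in cis:
        ci = etree.SubElement(apply_, f"{{{MATHML_NS}}}ci")
        ci.text = f" {name} "
    return math


def build_sbml(
    pathway: PathwayDefinition,
    k_default: float = 1.0,
    compartments: Mapping[str, str] | None = None,
    default_compartment: str | None = DEFAULT_COMPARTMENT,
    initial_amounts: Mapping[str, float] | None = None,
    templates: Mapping[str, str] = DEFAULT_TEMPLATES,
    level: int = 2,
    version: int = 4,
) -> str:
    """Render a pathway as an SBML XML document string.

    ``compartments`` maps cellular locations to compartment names; members
    with no (mapped) location fall into ``default_compartment``.  A member
    whose location is unmapped while no default compartment is configured is
    a configuration error, as is a non-positive ``k_default`` or an empty
    pathway.
    """
    if not pathway.members:
        raise InputError(f"pathway {pathway.name!r} has no members")
    if k_default <= 0:
        raise ConfigurationError(f"k_default must be positive, got {k_default}")
    for sign, template in templates.items():
        if template not in ("synthesis", "degradation"):
            raise ConfigurationError(f"unknown rate-law template {template!r} for {sign!r}")
    compartments = dict(compartments or {})
    initial_amounts = dict(initial_amounts or {})

    sid_of = _sanitize_ids(list(pathway.members))

    # resolve each member's compartment
    comp_of: dict[str, str] = {}
    for member in pathway.members:
        loc = pathway.locations.get(member)
        if loc is not None and loc in compartments:
            comp_of[member] = compartments[loc]
        elif loc is not None and default_compartment is None:
            raise ConfigurationError(
                f"member {member!r} has location {loc!r} with no compartment mapping "
                "and no default compartment is configured"
            )
        elif default_compartment is None:
            raise ConfigurationError(
                f"member {member!r} has no location and no default compartment is configured"
            )
        else:
            comp_of[member] = default_compartment

    nsmap = {None: SBML_NS}
    sbml = etree.Element(f"{{{SBML_NS}}}sbml", nsmap=nsmap)
    sbml.set("level", str(level))
    sbml.set("version", str(version))
    model = etree.SubElement(sbml, f"{{{SBML_NS}}}model")
    model.set("id", _ID_OK.sub("_", pathway.name) or "pathway")
    model.set("name", pathway.name)

    list_comp = etree.SubElement(model, f"{{{SBML_NS}}}listOfCompartments")
    for cname in sorted(set(comp_of.values())):
        comp = etree.SubElement(list_comp, f"{{{SBML_NS}}}compartment")
        comp.set("id", _ID_OK.sub("_", cname))
        comp.set("name", cname)
        comp.set("size", "1")

    list_sp = etree.SubElement(model, f"{{{SBML_NS}}}listOfSpecies")
    for member in sorted(pathway.members):
        sp = etree.SubElement(list_sp, f"{{{SBML_NS}}}species")
        sp.set("id", sid_of[member])
        sp.set("name", member)
        sp.set("compartment", _ID_OK.sub("_", comp_of[member]))
        sp.set("initialAmount", repr(float(initial_amounts.get(member, 1.0))))

    list_rx = etree.SubElement(model, f"{{{SBML_NS}}}listOfReactions")
    rx_ids: set[str] = set()
    for edge in pathway.interactions:
        template = templates.get(edge.sign)
        if template is None:
            raise ConfigurationError(f"no rate-law template for sign {edge.sign!r}")
        src, tgt = sid_of[edge.a], sid_of[edge.b]
        base = f"{'act' if edge.sign == 'activation' else 'inh'}_{src}_{tgt}"
        rid, k = base, 2
        while rid in rx_ids:
            rid = f"{base}_{k}"
            k += 1
        rx_ids.add(rid)
        rx = etree.SubElement(list_rx, f"{{{SBML_NS}}}reaction")
        rx.set("id", rid)
        rx.set("reversible", "false")
        if template == "synthesis":
            products = etree.SubElement(rx, f"{{{SBML_NS}}}listOfProducts")
            ref = etree.SubElement(products, f"{{{SBML_NS}}}speciesReference")
            ref.set("species", tgt)
            law_factors = ["k", src]
        else:  # degradation
            reactants = etree.SubElement(rx, f"{{{SBML_NS}}}listOfReactants")
            ref = etree.SubElement(reactants, f"{{{SBML_NS}}}speciesReference")
            ref.set("species", tgt)
            law_factors = ["k", src, tgt]
        modifiers = etree.SubElement(rx, f"{{{SBML_NS}}}listOfModifiers")
        mod = etree.SubElement(modifiers, f"{{{SBML_NS}}}modifierSpeciesReference")
        mod.set("species", src)
        law = etree.SubElement(rx, f"{{{SBML_NS}}}kineticLaw")
        annot = etree.SubElement(law, f"{{{SBML_NS}}}annotation")
        flag = etree.SubElement(annot, f"{{{ANNOT_NS}}}unparameterized", nsmap={"dn": ANNOT_NS})
        flag.set("comment", "placeholder first-order rate constant; supply measured kinetics")
        law.append(_math_times(law_factors))
        params = etree.SubElement(law, f"{{{SBML_NS}}}listOfParameters")
        par = etree.SubElement(params, f"{{{SBML_NS}}}parameter")
        par.set("id", "k")
        par.set("value", repr(float(k_default)))

    return etree.tostring(
        sbml, pretty_print=True, xml_declaration=True, encoding="UTF-8"
    ).decode("utf-8")


def validate_sbml(xml_text: str) -> list[str]:
    """Structural validation of an exported document; returns found issues.

    Checks id uniqueness, compartment references, species references in
    reactions, and that every ``ci`` symbol in a kinetic law is a declared
    species of that reaction or one of its local parameters.
    """
    issues: list[str] = []
    root = etree.fromstring(xml_text.encode("utf-8"))
    ns = {"s": SBML_NS, "m": MATHML_NS}
    comp_ids = [c.get("id") for c in root.findall(".//s:compartment", ns)]
    sp_ids = [s.get("id") for s in root.findall(".//s:species", ns)]
    rx_ids = [r.get("id") for r in root.findall(".//s:reaction", ns)]
    for label, ids in (("compartment", comp_ids), ("species", sp_ids), ("reaction", rx_ids)):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        if dupes:
            issues.append(f"duplicate {label} ids: {dupes}")
    for sp in root.findall(".//s:species", ns):
        if sp.get("compartment") not in comp_ids:
            issues.append(f"species {sp.get('id')} references unknown compartment")
    for rx in root.findall(".//s:reaction", ns):
        declared = {
            ref.get("species")
            for ref in rx.findall(".//s:speciesReference", ns)
            + rx.findall(".//s:modifierSpeciesReference", ns)
        }
        for ref in declared:
            if ref not in sp_ids:
                issues.append(f"reaction {rx.get('id')} references unknown species {ref}")
        local = {p.get("id") for p in rx.findall(".//s:parameter", ns)}
        for ci in rx.findall(".//m:ci", ns):
            symbol = (ci.text or "").strip()
            if symbol not in declared and symbol not in local:
                issues.append(
                    f"reaction {rx.get('id')}: kinetic-law symbol {symbol!r} "
                    "is neither a declared species of the reaction nor a local parameter"
                )
    return issues


def species_and_reaction_counts(xml_text: str) -> tuple[int, int]:
    """(species count, reaction count) of an SBML document, via re-parsing."""
    root = etree.fromstring(xml_text.encode("utf-8"))
    ns = {"s": SBML_NS}
    return (len(root.findall(".//s:species", ns)), len(root.findall(".//s:reaction", ns)))
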