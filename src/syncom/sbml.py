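"""SBML reader/writer for qualitative metabolic networks.

Supports the subset of SBML Level 3 core a qualitative model needs:
``listOfSpecies``, ``listOfReactions``, ``speciesReference`` and the
``reversible`` attribute. Kinetic laws, annotations, units, compartments
(beyond whatever suffix the species ids already carry) and stoichiometric
coefficients are ignored. Matching is by XML local name, so Level 2
documents with the same structure parse as well.

The writer emits a canonical document — species and reactions sorted by id,
fixed attribute order — so two writes of equal networks are byte-identical.
"""

from __future__ import annotations

import os

from lxml import etree

from syncom.core import MetabolicNetwork, Reaction, SyncomError, ValidationError

SBML_L3_NS = "http://www.sbml.org/sbml/level3/version1/core"


class SBMLParseError(SyncomError):
    """Raised for malformed or structurally invalid SBML input."""


def _local(tag) -> str:
    if not isinstance(tag, str):
        return ""
    return tag.rsplit("}", 1)[-1]


def _find_child(elem, name: str):
    for child in elem:
        if _local(child.tag) == name:
            return child
    return None


def _species_refs(list_elem) -> frozenset[str]:
    refs: set[str] = set()
    if list_elem is None:
        return frozenset()
    for child in list_elem:
        if _local(child.tag) == "speciesReference":
            sp = child.get("species")
            if sp:
                refs.add(sp)
    return frozenset(refs)


def parse_sbml_network(path: "str | os.PathLike") -> MetabolicNetwork:
    """Read one species' network from an SBML file.

    The model id (falling back to the file stem) becomes ``species_id``.
    Reactions with an empty reactant or product list are rejected with an
    error naming the offending reaction.
    """
    path = os.fspath(path)
    try:
        tree = etree.parse(path)
    except etree.XMLSyntaxError as exc:
        raise SBMLParseError(f"malformed XML in {path}: {exc}") from exc
    root = tree.getroot()
    if _local(root.tag) != "sbml":
        raise SBMLParseError(f"{path}: root element is not <sbml>")
    model = _find_child(root, "model")
    if model is None:
        raise SBMLParseError(f"{path}: no <model> element")
    species_id = model.get("id") or os.path.splitext(os.path.basename(path))[0]

    reactions: list[Reaction] = []
    list_of_reactions = _find_child(model, "listOfReactions")
    if list_of_reactions is not None:
        for rxn in list_of_reactions:
            if _local(rxn.tag) != "reaction":
                continue
            rid = rxn.get("id")
            if not rid:
                raise SBMLParseError(f"{path}: reaction without an id")
            reversible = (rxn.get("reversible") or "false").lower() == "true"
            reactants = _species_refs(_find_child(rxn, "listOfReactants"))
            products = _species_refs(_find_child(rxn, "listOfProducts"))
            if not reactants or not products:
                raise ValidationError(
                    f"{path}: reaction {rid!r} has an empty "
                    f"{'reactant' if not reactants else 'product'} list"
                )
            reactions.append(Reaction(rid, reactants, products, reversible))
    return MetabolicNetwork(species_id=species_id, reactions=tuple(reactions))


def write_sbml_network(network: MetabolicNetwork, path: "str | os.PathLike") -> None:
    """Write a network as canonical SBML Level 3 core.

    Element ordering is sorted by id, so output bytes depend only on the
    network's content.
    """
    if not network.reactions:
        raise ValidationError(
            f"refusing to write network {network.species_id!r} with no reactions"
        )
    nsmap = {None: SBML_L3_NS}
    root = etree.Element(f"{{{SBML_L3_NS}}}sbml", nsmap=nsmap)
    root.set("level", "3")
    root.set("version", "1")
    model = etree.SubElement(root, f"{{{SBML_L3_NS}}}model")
    model.set("id", network.species_id)

    los = etree.SubElement(model, f"{{{SBML_L3_NS}}}listOfSpecies")
    for cid in sorted(network.compounds):
        sp = etree.SubElement(los, f"{{{SBML_L3_NS}}}species")
        sp.set("id", cid)

    lor = etree.SubElement(model, f"{{{SBML_L3_NS}}}listOfReactions")
    for rxn in sorted(network.reactions, key=lambda r: r.id):
        re_ = etree.SubElement(lor, f"{{{SBML_L3_NS}}}reaction")
        re_.set("id", rxn.id)
        re_.set("reversible", "true" if rxn.reversible else "false")
        lre = etree.SubElement(re_, f"{{{SBML_L3_NS}}}listOfReactants")
        for cid in sorted(rxn.reactants):
            ref = etree.SubElement(lre, f"{{{SBML_L3_NS}}}speciesReference")
            ref.set("species", cid)
        lpr = etree.SubElement(re_, f"{{{SBML_L3_NS}}}listOfProducts")
        for cid in sorted(rxn.products):
            ref = etree.SubElement(lpr, f"{{{SBML_L3_NS}}}speciesReference")
            ref.set("species", cid)

    payload = etree.tostring(
        root, xml_declaration=True, encoding="UTF-8", pretty_print=True
    )
    with open(os.fspath(path), "wb") as fh:
        fh.write(payload)
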