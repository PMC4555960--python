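"""Serialization of the network and rate constants.

Two formats are supported: a YAML config mirroring the packaged mapping
table (the editable source of truth for the reaction <-> constant
assignment) and SBML Level 3 Version 2 core, written and parsed directly
as XML (species, reactions with stoichiometries, and the rate constants as
model parameters).  Round-tripping either format preserves the mapping.
"""

from __future__ import annotations

import yaml
from lxml import etree

from .network import (KineticParameters, Reaction, ReactionNetwork, Species,
                      ROM_K_INDICES)

SBML_NS = "http://www.sbml.org/sbml/level3/version2/core"
_E = "{%s}" % SBML_NS


# ---------------------------------------------------------------------------
# YAML
# ---------------------------------------------------------------------------

def network_to_dict(network: ReactionNetwork,
                    params: KineticParameters | None = None) -> dict:
    doc = {
        "plasmid_type": network.plasmid_type,
        "species": [{"name": s.name, "role": s.role} for s in network.species],
        "reactions": [{
            "id": r.rid, "k": r.k_index,
            "reactants": {n: s for n, s in r.reactants},
            "products": {n: s for n, s in r.products},
            **({"rom_dependent": True} if r.rom_dependent else {}),
            **({"gene_dosage": True} if r.gene_dosage else {}),
            **({"note": r.note} if r.note else {}),
        } for r in network.reactions],
    }
    if params is not None:
        doc["parameters"] = {i: {"value": v, "unit": params.units.get(i, "")}
                             for i, v in sorted(params.k.items())}
    return doc


def write_yaml(network: ReactionNetwork, path,
               params: KineticParameters | None = None) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(network_to_dict(network, params), fh, sort_keys=False)


def read_yaml(path) -> tuple[ReactionNetwork, KineticParameters | None]:
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    species = [Species(s["name"], s["role"]) for s in doc["species"]]
    reactions = [Reaction(
        rid=r["id"], k_index=int(r["k"]),
        reactants=tuple((n, int(s)) for n, s in (r.get("reactants") or {}).items()),
        products=tuple((n, int(s)) for n, s in (r.get("products") or {}).items()),
        rom_dependent=bool(r.get("rom_dependent", False)),
        gene_dosage=bool(r.get("gene_dosage", False)),
        note=r.get("note", "")) for r in doc["reactions"]]
    network = ReactionNetwork(species, reactions, doc["plasmid_type"])
    params = None
    if "parameters" in doc:
        params = KineticParameters(
            {int(i): float(p["value"]) for i, p in doc["parameters"].items()},
            doc["plasmid_type"],
            {int(i): p.get("unit", "") for i, p in doc["parameters"].items()})
    return network, params


# ---------------------------------------------------------------------------
# SBML Level 3
# ---------------------------------------------------------------------------

def write_sbml(network: ReactionNetwork, params: KineticParameters,
               path) -> None:
    """Write the network as an SBML Level 3 Version 2 core document."""
    sbml = etree.Element(_E + "sbml", nsmap={None: SBML_NS})
    sbml.set("level", "3")
    sbml.set("version", "2")
    model = etree.SubElement(sbml, _E + "model")
    model.set("id", f"ColE1_replication_control_{network.plasmid_type}_copy")
    model.set("substanceUnits", "mole")
    model.set("timeUnits", "second")

    comps = etree.SubElement(model, _E + "listOfCompartments")
    comp = etree.SubElement(comps, _E + "compartment")
    comp.set("id", "cell")
    comp.set("constant", "true")
    comp.set("spatialDimensions", "3")

    sp_list = etree.SubElement(model, _E + "listOfSpecies")
    for s in network.species:
        el = etree.SubElement(sp_list, _E + "species")
        el.set("id", s.name)
        el.set("name", s.role)
        el.set("compartment", "cell")
        el.set("hasOnlySubstanceUnits", "false")
        el.set("boundaryCondition", "false")
        el.set("constant", "false")

    par_list = etree.SubElement(model, _E + "listOfParameters")
    for i, v in sorted(params.k.items()):
        el = etree.SubElement(par_list, _E + "parameter")
        el.set("id", f"k{i}")
        el.set("value", repr(v))
        el.set("constant", "true")
        if i in params.units:
            el.set("name", params.units[i])

    rx_list = etree.SubElement(model, _E + "listOfReactions")
    for r in network.reactions:
        el = etree.SubElement(rx_list, _E + "reaction")
        el.set("id", r.rid)
        el.set("reversible", "false")
        el.set("name", r.note or r.rid)
        if r.gene_dosage:
            el.set("sboTerm", "SBO:0000589")   # genetic production
        if r.reactants:
            lor = etree.SubElement(el, _E + "listOfReactants")
            for name, stoich in r.reactants:
                ref = etree.SubElement(lor, _E + "speciesReference")
                ref.set("species", name)
                ref.set("stoichiometry", str(stoich))
                ref.set("constant", "true")
        if r.products:
            lop = etree.SubElement(el, _E + "listOfProducts")
            for name, stoich in r.products:
                ref = etree.SubElement(lop, _E + "speciesReference")
                ref.set("species", name)
                ref.set("stoichiometry", str(stoich))
                ref.set("constant", "true")
        kl = etree.SubElement(el, _E + "kineticLaw")
        math_el = etree.SubElement(
            kl, "{http://www.w3.org/1998/Math/MathML}math",
            nsmap={None: "http://www.w3.org/1998/Math/MathML"})
        mml = "{http://www.w3.org/1998/Math/MathML}"
        apply_el = etree.SubElement(math_el, mml + "apply")
        etree.SubElement(apply_el, mml + "times")
        ci = etree.SubElement(apply_el, mml + "ci")
        ci.text = f"k{r.k_index}"
        for name, stoich in r.reactants:
            for _ in range(stoich):
                ci = etree.SubElement(apply_el, mml + "ci")
                ci.text = name

    tree = etree.ElementTree(sbml)
    tree.write(str(path), pretty_print=True, xml_declaration=True,
               encoding="UTF-8")


def read_sbml(path) -> tuple[ReactionNetwork, KineticParameters]:
    """Parse an SBML document written by :func:`write_sbml`."""
    tree = etree.parse(str(path))
    model = tree.getroot().find(_E + "model")
    plasmid_type = "high" if "high" in model.get("id", "") else "low"
    species = [Species(el.get("id"), el.get("name"))
               for el in model.find(_E + "listOfSpecies")]
    k, units = {}, {}
    for el in model.find(_E + "listOfParameters"):
        idx = int(el.get("id")[1:])
        k[idx] = float(el.get("value"))
        if el.get("name"):
            units[idx] = el.get("name")
    reactions = []
    for el in model.find(_E + "listOfReactions"):
        def refs(tag):
            lst = el.find(_E + tag)
            if lst is None:
                return ()
            return tuple((ref.get("species"),
                          int(float(ref.get("stoichiometry", "1"))))
                         for ref in lst)
        kl = el.find(_E + "kineticLaw")
        mml = "{http://www.w3.org/1998/Math/MathML}"
        k_id = kl.find(f"{mml}math/{mml}apply/{mml}ci").text.strip()
        reactions.append(Reaction(
            rid=el.get("id"), k_index=int(k_id[1:]),
            reactants=refs("listOfReactants"), products=refs("listOfProducts"),
            rom_dependent=int(k_id[1:]) in ROM_K_INDICES,
            gene_dosage=el.get("sboTerm") == "SBO:0000589",
            note=el.get("name", "")))
    network = ReactionNetwork(species, reactions, plasmid_type)
    return network, KineticParameters(k, plasmid_type, units)
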