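"""Minimal SBML Level 3 Version 2 export/import for the reaction network.

The writer emits compartments, species (with the locale encoded in SBML ids),
and reactions with mass-action kinetic laws carrying the forward/reverse rate
constants as local parameters. The reader reconstructs the species census and
reaction count, so an export/import round trip reproduces the network
manifest. This is a purpose-built serializer for this package's networks,
not a general SBML toolkit.
"""

from __future__ import annotations

import re

from lxml import etree

from .network import Network

__all__ = ["export_sbml", "read_sbml_manifest"]

SBML_NS = "http://www.sbml.org/sbml/level3/version2/core"
MATHML_NS = "http://www.w3.org/1998/Math/MathML"


def _sbml_id(species_id: str) -> str:
    """SBML SId: alphanumerics/underscore, must not start with a digit."""
    sid = re.sub(r"[^A-Za-z0-9_]", "__", species_id)
    return f"s_{sid}"


def export_sbml(network: Network, path: str, model_id: str = "vegf_three_compartment") -> None:
    nsmap = {None: SBML_NS}
    root = etree.Element("sbml", nsmap=nsmap, level="3", version="2")
    model = etree.SubElement(root, "model", id=model_id)

    comps = etree.SubElement(model, "listOfCompartments")
    for comp in network.spec.compartments:
        etree.SubElement(
            comps, "compartment", id=comp, constant="false", spatialDimensions="3"
        )

    species_el = etree.SubElement(model, "listOfSpecies")
    for sp in network.species:
        etree.SubElement(
            species_el,
            "species",
            id=_sbml_id(sp.id),
            name=sp.id,
            compartment=sp.compartment,
            hasOnlySubstanceUnits="false",
            boundaryCondition="false",
            constant="false",
        )

    rxs = etree.SubElement(model, "listOfReactions")
    for j, rx in enumerate(network.reactions):
        r_el = etree.SubElement(
            rxs,
            "reaction",
            id=f"r{j}",
            reversible="true" if rx.koff is not None else "false",
        )
        r_el.set("name", f"{rx.kind}:{rx.rate_class}")
        if rx.reactants:
            lor = etree.SubElement(r_el, "listOfReactants")
            for sid in rx.reactants:
                etree.SubElement(
                    lor, "speciesReference", species=_sbml_id(sid),
                    stoichiometry="1", constant="true",
                )
        if rx.products:
            lop = etree.SubElement(r_el, "listOfProducts")
            for sid in rx.products:
                etree.SubElement(
                    lop, "speciesReference", species=_sbml_id(sid),
                    stoichiometry="1", constant="true",
                )
        kl = etree.SubElement(r_el, "kineticLaw")
        math = etree.SubElement(kl, f"{{{MATHML_NS}}}math")
        _mass_action_math(math, rx)
        lolp = etree.SubElement(kl, "listOfLocalParameters")
        etree.SubElement(lolp, "localParameter", id="kon", value=repr(float(rx.kon)))
        if rx.koff is not None:
            etree.SubElement(lolp, "localParameter", id="koff", value=repr(float(rx.koff)))

    etree.ElementTree(root).write(
        path, pretty_print=True, xml_declaration=True, encoding="UTF-8"
    )


def _mass_action_math(math_el, rx) -> None:
    """kon * prod(reactants) [- koff * prod(products) if reversible]."""

    def product_term(parent, rate_name: str, sids) -> None:
        apply_el = etree.SubElement(parent, f"{{{MATHML_NS}}}apply")
        etree.SubElement(apply_el, f"{{{MATHML_NS}}}times")
        ci = etree.SubElement(apply_el, f"{{{MATHML_NS}}}ci")
        ci.text = rate_name
        for sid in sids:
            ci = etree.SubElement(apply_el, f"{{{MATHML_NS}}}ci")
            ci.text = _sbml_id(sid)

    if rx.koff is not None:
        minus = etree.SubElement(math_el, f"{{{MATHML_NS}}}apply")
        etree.SubElement(minus, f"{{{MATHML_NS}}}minus")
        product_term(minus, "kon", rx.reactants)
        product_term(minus, "koff", rx.products)
    else:
        product_term(math_el, "kon", rx.reactants)


def read_sbml_manifest(path: str) -> dict:
    """Parse an SBML file and return the species census and reaction count.

    Returns {"counts": {compartment: n}, "total": int, "n_reactions": int,
    "species": [original ids]}.
    """
    tree = etree.parse(path)
    ns = {"s": SBML_NS}
    counts: dict[str, int] = {}
    names: list[str] = []
    for sp in tree.findall(".//s:listOfSpecies/s:species", ns):
        comp = sp.get("compartment")
        counts[comp] = counts.get(comp, 0) + 1
        names.append(sp.get("name") or sp.get("id"))
    n_rx = len(tree.findall(".//s:listOfReactions/s:reaction", ns))
    return {
        "counts": counts,
        "total": sum(counts.values()),
        "n_reactions": n_rx,
        "species": names,
    }
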