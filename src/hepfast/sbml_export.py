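"""Optional export of the model as SBML Level 3 Version 2.

The document carries the four compartments (liver, muscle, adipose,
plasma) with their volumes, the 23 species, the 81 parameters and the 45
registry reactions with kinetic laws as content MathML (generated through
sympy).  Reversible net reactions are marked ``reversible="true"``.  The
writer emits plain XML via lxml; in bolus mode the two dietary input
fluxes are zero-rate boundary reactions.
"""

from __future__ import annotations

import sympy as sp
from lxml import etree

from ._symbolic import symbolic_rates
from .model_core import (PARAM_NAMES, REACTIONS, STATE_COMPARTMENT,
                         STATE_NAMES, STATE_UNITS, DEFAULT_INITIAL,
                         ParameterSet)

__all__ = ["model_to_sbml"]

SBML_NS = "http://www.sbml.org/sbml/level3/version2/core"
MATHML_NS = "http://www.w3.org/1998/Math/MathML"

_REVERSIBLE = {"v9", "v25", "v27", "v30", "v42"}


def _mathml(expr: sp.Expr) -> etree._Element:
    """Content MathML element for a sympy expression."""
    from sympy.printing.mathml import mathml
    body = mathml(expr)
    # sympy renders subscripted symbols with an mml-prefixed presentation
    # tag inside the content markup; declare the prefix alongside
    xml = (f'<math xmlns="{MATHML_NS}" xmlns:mml="{MATHML_NS}">'
           f'{body}</math>')
    return etree.fromstring(xml.encode())


def model_to_sbml(params: ParameterSet | None = None,
                  model_id: str = "hepatic_lipid_metabolism") -> bytes:
    """Serialize the model as an SBML L3V2 document (UTF-8 bytes)."""
    from . import model_core
    params = params or model_core.default_parameters()

    nsmap = {None: SBML_NS}
    sbml = etree.Element("sbml", nsmap=nsmap,
                         attrib={"level": "3", "version": "2"})
    model = etree.SubElement(sbml, "model", id=model_id)

    compartments = etree.SubElement(model, "listOfCompartments")
    volumes = {"liver": params["alpha_L"], "muscle": params["alpha_M"],
               "adipose": params["alpha_A"], "plasma": 1.0}
    for cid, size in volumes.items():
        etree.SubElement(compartments, "compartment", id=cid,
                         size=repr(float(size)), constant="true")

    species_el = etree.SubElement(model, "listOfSpecies")
    for name in STATE_NAMES:
        init = DEFAULT_INITIAL[name]
        attrib = {
            "id": name,
            "compartment": STATE_COMPARTMENT[name],
            "hasOnlySubstanceUnits": "false",
            "boundaryCondition": "false",
            "constant": "false",
        }
        if init is not None:
            attrib["initialConcentration"] = repr(float(init))
        sp_el = etree.SubElement(species_el, "species", attrib)
        sp_el.append(etree.Comment(f" unit: {STATE_UNITS[name]} "))

    params_el = etree.SubElement(model, "listOfParameters")
    for name in PARAM_NAMES:
        etree.SubElement(params_el, "parameter", id=name,
                         value=repr(params[name]), constant="true")

    rates = symbolic_rates()
    reactions_el = etree.SubElement(model, "listOfReactions")
    for rxn in REACTIONS:
        r_el = etree.SubElement(
            reactions_el, "reaction", id=rxn.rid,
            name=rxn.name,
            reversible="true" if rxn.rid in _REVERSIBLE else "false")
        reactants = [(s, -f) for s, f in rxn.stoich.items() if f < 0]
        products = [(s, f) for s, f in rxn.stoich.items() if f > 0]
        if reactants:
            lo = etree.SubElement(r_el, "listOfReactants")
            for sname, stoich in reactants:
                etree.SubElement(lo, "speciesReference", species=sname,
                                 stoichiometry=repr(float(stoich)),
                                 constant="true")
        if products:
            lo = etree.SubElement(r_el, "listOfProducts")
            for sname, stoich in products:
                etree.SubElement(lo, "speciesReference", species=sname,
                                 stoichiometry=repr(float(stoich)),
                                 constant="true")
        law = etree.SubElement(r_el, "kineticLaw")
        law.append(_mathml(rates[rxn.rid]))

    return etree.tostring(sbml, xml_declaration=True, encoding="UTF-8",
                          pretty_print=True)
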