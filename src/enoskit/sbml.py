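"""SBML Level 3 export of the reaction network.

The document is written directly as SBML L3V2 XML (compartments, species,
global parameters, reactions with MathML kinetic laws).  Mass-action,
Michaelis-Menten and the gated transport fluxes are emitted as explicit
MathML expressions over the named global parameters, so the exported file
is a faithful, self-contained statement of the model equations.

``read_sbml_summary`` parses an exported document back (species count,
parameter values, reaction count) for round-trip checks.
"""

from __future__ import annotations

from lxml import etree

from .network import ReactionNetwork, RateConstant

SBML_NS = "http://www.sbml.org/sbml/level3/version2/core"
MATHML_NS = "http://www.w3.org/1998/Math/MathML"


def _m(tag):
    return f"{{{MATHML_NS}}}{tag}"


def _ci(parent, name):
    el = etree.SubElement(parent, _m("ci"))
    el.text = f" {name} "
    return el


def _cn(parent, value):
    el = etree.SubElement(parent, _m("cn"))
    el.text = f" {value!r} "
    return el


def _apply(parent, op):
    ap = etree.SubElement(parent, _m("apply"))
    etree.SubElement(ap, _m(op))
    return ap


def _sanitize(name: str) -> str:
    return name.replace(".", "_")


def _rate_constant_math(parent, rc: RateConstant):
    """MathML for a product of named constants with integer exponents."""
    terms = []
    if rc.factor != 1.0:
        terms.append(("__factor__", rc.factor))
    pos = [(n, e) for n, e in rc.terms if e > 0]
    neg = [(n, -e) for n, e in rc.terms if e < 0]

    def emit_product(par, items, factor):
        elems = ([factor] if factor is not None else []) + items
        if len(elems) == 1 and factor is None:
            n, e = items[0]
            _emit_pow(par, n, e)
            return
        times = _apply(par, "times")
        if factor is not None:
            _cn(times, factor)
        for n, e in items:
            _emit_pow(times, n, e)

    def _emit_pow(par, n, e):
        if e == 1:
            _ci(par, n)
        else:
            p = _apply(par, "power")
            _ci(p, n)
            _cn(p, e)

    factor = rc.factor if rc.factor != 1.0 else None
    if neg:
        div = _apply(parent, "divide")
        if pos or factor is not None:
            emit_product(div, pos, factor)
        else:
            _cn(div, 1.0)
        emit_product(div, neg, None)
    else:
        if not pos and factor is not None:
            _cn(parent, factor)
        else:
            emit_product(parent, pos, factor)


def _kinetic_math(parent, rxn, network):
    rl = rxn.rate_law
    if rl.kind == "mass_action":
        if rxn.reactants:
            times = _apply(parent, "times")
            _rate_constant_math(times, rl.kf)
            for sp, st in sorted(rxn.reactants.items()):
                if st == 1:
                    _ci(times, sp)
                else:
                    p = _apply(times, "power")
                    _ci(p, sp)
                    _cn(p, st)
        else:
            _rate_constant_math(parent, rl.kf)
    elif rl.kind == "michaelis_menten":
        sub = next(iter(rxn.reactants)) if rxn.reactants else None
        if sub is None:
            # clamped substrate pool named via the compiled patch table
            from .odes import CompiledModel  # noqa: F401 (documentation)
            sub = {"ip3_production": "PIP2",
                   "cgmp_synthesis": "GTP"}[rxn.name]
        div = _apply(parent, "divide")
        times = _apply(div, "times")
        _rate_constant_math(times, rl.kcat)
        _ci(times, rl.enzyme)
        _ci(times, sub)
        plus = _apply(div, "plus")
        _rate_constant_math(plus, rl.Km)
        _ci(plus, sub)
    else:  # hill_flux
        times = _apply(parent, "times")
        _rate_constant_math(times, rl.Imax)
        div = _apply(times, "divide")
        if rl.inhibited:
            p = _apply(div, "power")
            _rate_constant_math(p, rl.K)
            _cn(p, rl.n)
        else:
            p = _apply(div, "power")
            _ci(p, rl.activator)
            _cn(p, rl.n)
        plus = _apply(div, "plus")
        pk = _apply(plus, "power")
        _rate_constant_math(pk, rl.K)
        _cn(pk, rl.n)
        pa = _apply(plus, "power")
        _ci(pa, rl.activator)
        _cn(pa, rl.n)
        if rl.driving is not None:
            minus = _apply(times, "minus")
            _ci(minus, rl.driving[0])
            _ci(minus, rl.driving[1])
        if rl.modifier is not None:
            div2 = _apply(times, "divide")
            _ci(div2, rl.modifier[0])
            _cn(div2, rl.modifier[1])


def export_sbml(network: ReactionNetwork, path=None) -> bytes:
    """Serialize the network as an SBML L3V2 document.

    Returns the document bytes; also writes to ``path`` when given.
    """
    nsmap = {None: SBML_NS}
    root = etree.Element(f"{{{SBML_NS}}}sbml", nsmap=nsmap)
    root.set("level", "3")
    root.set("version", "2")
    model = etree.SubElement(root, f"{{{SBML_NS}}}model")
    model.set("id", "vegf_tsp1_enos")
    model.set("timeUnits", "dimensionless")

    loc = etree.SubElement(model, f"{{{SBML_NS}}}listOfCompartments")
    for c in network.compartments.values():
        el = etree.SubElement(loc, f"{{{SBML_NS}}}compartment")
        el.set("id", c.name)
        el.set("constant", "true")
        if c.volume_L is not None:
            el.set("size", repr(c.volume_L))
        el.set("spatialDimensions", "3")

    los = etree.SubElement(model, f"{{{SBML_NS}}}listOfSpecies")
    for s in network.species:
        el = etree.SubElement(los, f"{{{SBML_NS}}}species")
        el.set("id", s.name)
        el.set("compartment", s.compartment)
        el.set("initialConcentration", repr(s.initial))
        el.set("hasOnlySubstanceUnits", "false")
        el.set("boundaryCondition", "true" if s.clamped else "false")
        el.set("constant", "false")

    lop = etree.SubElement(model, f"{{{SBML_NS}}}listOfParameters")
    for name in network.params.names():
        el = etree.SubElement(lop, f"{{{SBML_NS}}}parameter")
        el.set("id", _sanitize(name))
        el.set("value", repr(network.params[name]))
        el.set("constant", "true")

    lor = etree.SubElement(model, f"{{{SBML_NS}}}listOfReactions")
    for rxn in network.reactions:
        el = etree.SubElement(lor, f"{{{SBML_NS}}}reaction")
        el.set("id", _sanitize(rxn.name))
        el.set("reversible", "false")
        if rxn.reactants:
            lr = etree.SubElement(el, f"{{{SBML_NS}}}listOfReactants")
            for sp, st in sorted(rxn.reactants.items()):
                ref = etree.SubElement(lr, f"{{{SBML_NS}}}speciesReference")
                ref.set("species", sp)
                ref.set("stoichiometry", repr(float(st)))
                ref.set("constant", "true")
        if rxn.products:
            lp = etree.SubElement(el, f"{{{SBML_NS}}}listOfProducts")
            for sp, st in sorted(rxn.products.items()):
                ref = etree.SubElement(lp, f"{{{SBML_NS}}}speciesReference")
                ref.set("species", sp)
                ref.set("stoichiometry", repr(float(st)))
                ref.set("constant", "true")
        mods = set()
        rl = rxn.rate_law
        if rl.enzyme:
            mods.add(rl.enzyme)
        if rl.activator and rl.activator not in rxn.reactants:
            mods.add(rl.activator)
        if rl.modifier:
            mods.add(rl.modifier[0])
        if rl.driving:
            mods.update(sp for sp in rl.driving if sp not in rxn.reactants)
        mods -= set(rxn.products)
        if mods:
            lm = etree.SubElement(el, f"{{{SBML_NS}}}listOfModifiers")
            for sp in sorted(mods):
                ref = etree.SubElement(
                    lm, f"{{{SBML_NS}}}modifierSpeciesReference")
                ref.set("species", sp)
        kl = etree.SubElement(el, f"{{{SBML_NS}}}kineticLaw")
        math = etree.SubElement(kl, _m("math"),
                                nsmap={None: MATHML_NS})
        _kinetic_math(math, rxn, network)

    doc = etree.tostring(root, xml_declaration=True, encoding="UTF-8",
                         pretty_print=True)
    if path is not None:
        with open(path, "wb") as fh:
            fh.write(doc)
    return doc


def read_sbml_summary(source) -> dict:
    """Parse an SBML document (bytes or path) into a structural summary."""
    if isinstance(source, bytes):
        root = etree.fromstring(source)
    else:
        root = etree.parse(str(source)).getroot()
    ns = {"s": SBML_NS}
    species = root.findall(".//s:listOfSpecies/s:species", ns)
    params = root.findall(".//s:listOfParameters/s:parameter", ns)
    reactions = root.findall(".//s:listOfReactions/s:reaction", ns)
    comps = root.findall(".//s:listOfCompartments/s:compartment", ns)
    return {
        "level": root.get("level"),
        "version": root.get("version"),
        "n_species": len(species),
        "n_reactions": len(reactions),
        "n_compartments": len(comps),
        "parameter_values": {p.get("id"): float(p.get("value"))
                             for p in params},
        "initial_concentrations": {
            s.get("id"): float(s.get("initialConcentration"))
            for s in species},
    }
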