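"""SBML Level 3 (core) import/export.

The model is serialized to SBML Level 3 Version 2 core with mass-action
kinetic laws written as MathML products (rate constant times reactant and
modifier amounts).  Species roles, parameter unit tags and conserved-pool
declarations — which SBML core has no slot for — travel in a small custom
annotation namespace, so that write -> read is the identity on the
structural content (species, reactions, parameters, initial amounts).
"""

from __future__ import annotations

from lxml import etree

from .network import COMPARTMENTS, ModelSpec, RateParameter, ReactionDef, SpeciesDef

SBML_NS = "http://www.sbml.org/sbml/level3/version2/core"
MATHML_NS = "http://www.w3.org/1998/Math/MathML"
ANNOT_NS = "urn:chondrosim:annotations"


class SBMLParseError(ValueError):
    """Malformed SBML document; the message carries the location."""


def _q(tag, ns=SBML_NS):
    return f"{{{ns}}}{tag}"


def write_sbml(model: ModelSpec) -> str:
    """Serialize a model to an SBML Level 3 core document (string)."""
    nsmap = {None: SBML_NS, "cs": ANNOT_NS}
    root = etree.Element(_q("sbml"), nsmap=nsmap)
    root.set("level", "3")
    root.set("version", "2")
    mdl = etree.SubElement(root, _q("model"))
    mdl.set("id", model.name)
    mdl.set("name", f"{model.name} v{model.version}")

    annot = etree.SubElement(mdl, _q("annotation"))
    meta = etree.SubElement(annot, _q("model-meta", ANNOT_NS))
    meta.set("version", model.version)
    for pool, members in model.conserved_pools.items():
        el = etree.SubElement(meta, _q("conserved-pool", ANNOT_NS))
        el.set("name", pool)
        el.set("members", " ".join(members))

    locomp = etree.SubElement(mdl, _q("listOfCompartments"))
    for comp in model.compartments:
        c = etree.SubElement(locomp, _q("compartment"))
        c.set("id", comp)
        c.set("size", "1")
        c.set("spatialDimensions", "3")
        c.set("constant", "true")

    losp = etree.SubElement(mdl, _q("listOfSpecies"))
    for sp in model.species:
        s = etree.SubElement(losp, _q("species"))
        s.set("id", sp.id)
        s.set("name", sp.display_name)
        s.set("compartment", sp.compartment)
        s.set("initialAmount", str(sp.initial_amount))
        s.set("hasOnlySubstanceUnits", "true")
        s.set("boundaryCondition", "false")
        s.set("constant", "false")
        a = etree.SubElement(s, _q("annotation"))
        etree.SubElement(a, _q("species-meta", ANNOT_NS)).set("role", sp.role)

    lop = etree.SubElement(mdl, _q("listOfParameters"))
    for p in model.parameters:
        e = etree.SubElement(lop, _q("parameter"))
        e.set("id", p.id)
        e.set("value", repr(p.value))
        e.set("constant", "true")
        a = etree.SubElement(e, _q("annotation"))
        me = etree.SubElement(a, _q("parameter-meta", ANNOT_NS))
        me.set("units", p.units)
        if p.description:
            me.set("description", p.description)

    lor = etree.SubElement(mdl, _q("listOfReactions"))
    for r in model.reactions:
        e = etree.SubElement(lor, _q("reaction"))
        e.set("id", r.id)
        e.set("reversible", "false")
        if r.anchor:
            a = etree.SubElement(e, _q("annotation"))
            etree.SubElement(a, _q("reaction-meta", ANNOT_NS)).set("anchor", r.anchor)
        if r.reactants:
            lo = etree.SubElement(e, _q("listOfReactants"))
            for sid, sto in r.reactants.items():
                sr = etree.SubElement(lo, _q("speciesReference"))
                sr.set("species", sid)
                sr.set("stoichiometry", str(sto))
                sr.set("constant", "true")
        if r.products:
            lo = etree.SubElement(e, _q("listOfProducts"))
            for sid, sto in r.products.items():
                sr = etree.SubElement(lo, _q("speciesReference"))
                sr.set("species", sid)
                sr.set("stoichiometry", str(sto))
                sr.set("constant", "true")
        if r.modifiers:
            lo = etree.SubElement(e, _q("listOfModifiers"))
            for sid in r.modifiers:
                sr = etree.SubElement(lo, _q("modifierSpeciesReference"))
                sr.set("species", sid)
        kl = etree.SubElement(e, _q("kineticLaw"))
        math = etree.SubElement(kl, _q("math", MATHML_NS))
        factors = [r.rate_constant]
        for sid, sto in r.reactants.items():
            factors.extend([sid] * sto)
        factors.extend(r.modifiers)
        if len(factors) == 1:
            ci = etree.SubElement(math, _q("ci", MATHML_NS))
            ci.text = factors[0]
        else:
            ap = etree.SubElement(math, _q("apply", MATHML_NS))
            etree.SubElement(ap, _q("times", MATHML_NS))
            for f in factors:
                ci = etree.SubElement(ap, _q("ci", MATHML_NS))
                ci.text = f

    return etree.tostring(root, pretty_print=True, xml_declaration=True,
                          encoding="UTF-8").decode()


def _sref(parent, list_tag, ref_tag, line):
    out = {}
    lo = parent.find(_q(list_tag))
    if lo is None:
        return out
    for sr in lo.findall(_q(ref_tag)):
        sid = sr.get("species")
        if sid is None:
            raise SBMLParseError(f"speciesReference without species (line {sr.sourceline})")
        sto = int(float(sr.get("stoichiometry", "1")))
        out[sid] = sto
    return out


def read_sbml(document: str) -> ModelSpec:
    """Parse an SBML Level 3 core document back into a :class:`ModelSpec`."""
    try:
        root = etree.fromstring(document.encode() if isinstance(document, str) else document)
    except etree.XMLSyntaxError as exc:
        raise SBMLParseError(f"not well-formed XML: {exc}") from exc
    if root.tag != _q("sbml"):
        raise SBMLParseError(f"root element is {root.tag!r}, expected SBML level 3")
    if root.get("level") != "3":
        raise SBMLParseError(f"unsupported SBML level {root.get('level')!r}")
    mdl = root.find(_q("model"))
    if mdl is None:
        raise SBMLParseError("document has no <model> element")

    version = "1.0"
    conserved = {}
    annot = mdl.find(_q("annotation"))
    if annot is not None:
        meta = annot.find(_q("model-meta", ANNOT_NS))
        if meta is not None:
            version = meta.get("version", version)
            for el in meta.findall(_q("conserved-pool", ANNOT_NS)):
                conserved[el.get("name")] = el.get("members", "").split()

    compartments = []
    locomp = mdl.find(_q("listOfCompartments"))
    if locomp is not None:
        compartments = [c.get("id") for c in locomp.findall(_q("compartment"))]
    if not compartments:
        compartments = list(COMPARTMENTS)

    species = []
    losp = mdl.find(_q("listOfSpecies"))
    if losp is not None:
        for s in losp.findall(_q("species")):
            role = "protein"
            a = s.find(_q("annotation"))
            if a is not None:
                me = a.find(_q("species-meta", ANNOT_NS))
                if me is not None:
                    role = me.get("role", role)
            try:
                species.append(SpeciesDef(
                    id=s.get("id"),
                    display_name=s.get("name", s.get("id")),
                    compartment=s.get("compartment"),
                    initial_amount=int(float(s.get("initialAmount", "0"))),
                    role=role,
                ))
            except (TypeError, ValueError) as exc:
                raise SBMLParseError(
                    f"invalid species {s.get('id')!r} (line {s.sourceline}): {exc}"
                ) from exc
    declared = {sp.id for sp in species}

    parameters = []
    lop = mdl.find(_q("listOfParameters"))
    if lop is not None:
        for p in lop.findall(_q("parameter")):
            units, desc = "per_second", ""
            a = p.find(_q("annotation"))
            if a is not None:
                me = a.find(_q("parameter-meta", ANNOT_NS))
                if me is not None:
                    units = me.get("units", units)
                    desc = me.get("description", "")
            try:
                parameters.append(RateParameter(p.get("id"), float(p.get("value", "0")),
                                                units, desc))
            except (TypeError, ValueError) as exc:
                raise SBMLParseError(
                    f"invalid parameter {p.get('id')!r} (line {p.sourceline}): {exc}"
                ) from exc
    param_ids = {p.id for p in parameters}

    reactions = []
    lor = mdl.find(_q("listOfReactions"))
    if lor is not None:
        for e in lor.findall(_q("reaction")):
            rid = e.get("id")
            reactants = _sref(e, "listOfReactants", "speciesReference", e.sourceline)
            products = _sref(e, "listOfProducts", "speciesReference", e.sourceline)
            modifiers = []
            lo = e.find(_q("listOfModifiers"))
            if lo is not None:
                modifiers = [sr.get("species")
                             for sr in lo.findall(_q("modifierSpeciesReference"))]
            anchor = ""
            a = e.find(_q("annotation"))
            if a is not None:
                me = a.find(_q("reaction-meta", ANNOT_NS))
                if me is not None:
                    anchor = me.get("anchor", "")
            kl = e.find(_q("kineticLaw"))
            if kl is None:
                raise SBMLParseError(f"reaction {rid!r} has no kineticLaw (line {e.sourceline})")
            cis = kl.findall(f".//{_q('ci', MATHML_NS)}")
            rate_constant = None
            for ci in cis:
                name = (ci.text or "").strip()
                if name in param_ids:
                    rate_constant = name
                    break
            if rate_constant is None:
                raise SBMLParseError(
                    f"kineticLaw of {rid!r} names no declared parameter (line {kl.sourceline})"
                )
            undeclared = (set(reactants) | set(products) | set(modifiers)) - declared
            if undeclared:
                raise SBMLParseError(
                    f"reaction {rid!r} references undeclared species "
                    f"{sorted(undeclared)} (line {e.sourceline})"
                )
            reactions.append(ReactionDef(rid, reactants, products, tuple(modifiers),
                                         rate_constant, anchor))

    name = mdl.get("id", "model")
    return ModelSpec(name=name, version=version, compartments=tuple(compartments),
                     species=species, reactions=reactions, parameters=parameters,
                     conserved_pools=conserved)
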