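"""SBML Level 2 Version 4 subset import/export.

Supported elements: compartments, species, global and reaction-local
parameters, reactions with content-MathML kinetic laws, and modifier
species references.  Rules, events, constraints and function definitions
are deliberately unsupported and raise :class:`UnsupportedSbmlError` naming
the offending element.  Regime information (the stochastic/deterministic
partition) has no SBML representation: on export the caller states whether
the document is meant to be read stochastically or continuously, and on
import every species comes back continuous (overridable), so a round trip
keeps the structure but drops the partition.
"""

from __future__ import annotations

import xml.etree.ElementTree as ET
from typing import Mapping

from . import expressions as ex
from . import model as mdl
from .coloured import ColouredNet, unfold
from .model import HybridPetriNet, Place, Transition

__all__ = ["SbmlError", "UnsupportedSbmlError", "import_sbml", "export_sbml"]

SBML_NS = "http://www.sbml.org/sbml/level2/version4"
MATHML_NS = "http://www.w3.org/1998/Math/MathML"

_UNSUPPORTED_LISTS = {
    "listOfRules": "rule",
    "listOfEvents": "event",
    "listOfConstraints": "constraint",
    "listOfFunctionDefinitions": "functionDefinition",
    "listOfInitialAssignments": "initialAssignment",
}


class SbmlError(Exception):
    pass


class UnsupportedSbmlError(SbmlError):
    pass


def _q(tag: str, ns: str = SBML_NS) -> str:
    return f"{{{ns}}}{tag}"


# ---------------------------------------------------------------------------
# MathML -> Expression
# ---------------------------------------------------------------------------

_MATHML_OPS = {"plus": "+", "minus": "-", "times": "*", "divide": "/",
               "power": "^"}


def _mathml_to_expr(node, symbols: ex.SymbolTable,
                    rename: Mapping[str, str]) -> ex.Expression:
    tag = node.tag.replace(f"{{{MATHML_NS}}}", "")
    if tag == "math":
        children = list(node)
        if len(children) != 1:
            raise SbmlError("math element must have exactly one child")
        return _mathml_to_expr(children[0], symbols, rename)
    if tag == "cn":
        text = (node.text or "").strip()
        if node.get("type") == "e-notation":
            sep = node.find(_q("sep", MATHML_NS))
            mantissa = float(text)
            expo = float((sep.tail or "0").strip()) if sep is not None else 0.0
            return ex.Num(mantissa * 10.0 ** expo)
        if node.get("type") == "rational":
            sep = node.find(_q("sep", MATHML_NS))
            den = float((sep.tail or "1").strip()) if sep is not None else 1.0
            return ex.Num(float(text) / den)
        return ex.Num(float(text))
    if tag == "ci":
        name = (node.text or "").strip()
        name = rename.get(name, name)
        if name in symbols.places:
            return ex.Ref(name, "place")
        if name in symbols.params:
            return ex.Ref(name, "param")
        raise SbmlError(f"kinetic law references unknown identifier {name!r}")
    if tag == "apply":
        children = list(node)
        op_tag = children[0].tag.replace(f"{{{MATHML_NS}}}", "")
        args = [_mathml_to_expr(c, symbols, rename) for c in children[1:]]
        if op_tag in _MATHML_OPS:
            op = _MATHML_OPS[op_tag]
            if op_tag == "minus" and len(args) == 1:
                return ex.Neg(args[0])
            if len(args) < 2:
                raise SbmlError(f"operator {op_tag!r} needs two operands")
            node_expr = args[0]
            for a in args[1:]:
                node_expr = ex.BinOp(op, node_expr, a)
            return node_expr
        raise UnsupportedSbmlError(
            f"unsupported MathML operator element {op_tag!r}")
    if tag == "csymbol":
        raise UnsupportedSbmlError(
            f"unsupported MathML csymbol {(node.text or '').strip()!r}")
    raise UnsupportedSbmlError(f"unsupported MathML element {tag!r}")


# ---------------------------------------------------------------------------
# Expression -> MathML
# ---------------------------------------------------------------------------

def _expr_to_mathml(expr: ex.Expression) -> ET.Element:
    if isinstance(expr, ex.Num):
        cn = ET.Element(_q("cn", MATHML_NS))
        v = expr.value
        if v == int(v):
            cn.set("type", "integer")
            cn.text = str(int(v))
        else:
            cn.text = repr(v)
        return cn
    if isinstance(expr, ex.Ref):
        ci = ET.Element(_q("ci", MATHML_NS))
        ci.text = expr.name
        return ci
    if isinstance(expr, ex.Neg):
        ap = ET.Element(_q("apply", MATHML_NS))
        ap.append(ET.Element(_q("minus", MATHML_NS)))
        ap.append(_expr_to_mathml(expr.operand))
        return ap
    if isinstance(expr, ex.BinOp):
        tag = {v: k for k, v in _MATHML_OPS.items()}[expr.op]
        ap = ET.Element(_q("apply", MATHML_NS))
        ap.append(ET.Element(_q(tag, MATHML_NS)))
        ap.append(_expr_to_mathml(expr.left))
        ap.append(_expr_to_mathml(expr.right))
        return ap
    raise SbmlError(
        f"expression node {type(expr).__name__} has no SBML representation")


# ---------------------------------------------------------------------------
# Import
# ---------------------------------------------------------------------------

def import_sbml(document: str,
                discrete_species: tuple = ()) -> HybridPetriNet:
    """Build a net from an SBML L2V4 document (string or file path).

    Species become continuous places (ids in ``discrete_species`` become
    discrete), reactions become continuous transitions (one per direction
    for reversible reactions, splitting the kinetic law on its top-level
    subtraction), local parameters are namespaced ``reaction.param``, and
    boundary-condition species are connected by modifier arcs only (their
    marking never changes).
    """
    text = document
    if "<" not in document:  # path, not XML text
        with open(document) as fh:
            text = fh.read()
    try:
        root = ET.fromstring(text)
    except ET.ParseError as err:
        raise SbmlError(f"not well-formed XML: {err}") from err
    model = root.find(_q("model"))
    if model is None:
        raise SbmlError("document has no <model> element")
    for list_tag, what in _UNSUPPORTED_LISTS.items():
        lst = model.find(_q(list_tag))
        if lst is not None and len(lst):
            ident = next(iter(lst)).get("id") or next(iter(lst)).get("variable") \
                or "?"
            raise UnsupportedSbmlError(
                f"unsupported element: {what} {ident!r} (rules, events and "
                "constraints are outside the supported SBML subset)")

    net = HybridPetriNet(model.get("id") or model.get("name") or "sbml_model")

    compartments: dict[str, float] = {}
    for comp in model.iter(_q("compartment")):
        size = float(comp.get("size", comp.get("volume", 1.0) or 1.0))
        compartments[comp.get("id")] = size
        net.set_parameter(comp.get("id"), size)

    boundary: set = set()
    for sp in model.iter(_q("species")):
        sid = sp.get("id")
        if sp.get("initialAmount") is not None:
            amount = float(sp.get("initialAmount"))
        elif sp.get("initialConcentration") is not None:
            amount = (float(sp.get("initialConcentration"))
                      * compartments.get(sp.get("compartment"), 1.0))
        else:
            amount = 0.0
        kind = "discrete" if sid in discrete_species else "continuous"
        net.add_place(Place(sid, kind, amount))
        if sp.get("boundaryCondition") in ("true", "1"):
            boundary.add(sid)

    for par in model.findall(f"{_q('listOfParameters')}/{_q('parameter')}"):
        net.set_parameter(par.get("id"), float(par.get("value", 0.0)))

    for rx in model.iter(_q("reaction")):
        rid = rx.get("id")
        reversible = rx.get("reversible", "true") in ("true", "1")
        reactants, products, modifiers = [], [], []
        for ref in rx.findall(f"{_q('listOfReactants')}/{_q('speciesReference')}"):
            reactants.append((ref.get("species"),
                              float(ref.get("stoichiometry", 1.0))))
        for ref in rx.findall(f"{_q('listOfProducts')}/{_q('speciesReference')}"):
            products.append((ref.get("species"),
                             float(ref.get("stoichiometry", 1.0))))
        for ref in rx.findall(f"{_q('listOfModifiers')}/"
                              f"{_q('modifierSpeciesReference')}"):
            modifiers.append(ref.get("species"))

        klaw = rx.find(_q("kineticLaw"))
        if klaw is None:
            raise SbmlError(f"reaction {rid!r} has no kinetic law")
        rename = {}
        for par in klaw.findall(f"{_q('listOfParameters')}/{_q('parameter')}"):
            scoped = f"{rid}.{par.get('id')}"
            net.set_parameter(scoped, float(par.get("value", 0.0)))
            rename[par.get("id")] = scoped
        math = klaw.find(_q("math", MATHML_NS))
        if math is None:
            raise SbmlError(f"kinetic law of {rid!r} has no math element")
        expr = _mathml_to_expr(math, net.symbols(), rename)

        if reversible:
            if not (isinstance(expr, ex.BinOp) and expr.op == "-"):
                raise UnsupportedSbmlError(
                    f"reversible reaction {rid!r}: kinetic law is not a "
                    "top-level difference (forward minus backward) and "
                    "cannot be split into two irreversible transitions")
            _add_reaction(net, f"{rid}_fwd", reactants, products, modifiers,
                          expr.left, boundary)
            _add_reaction(net, f"{rid}_rev", products, reactants, modifiers,
                          expr.right, boundary)
        else:
            _add_reaction(net, rid, reactants, products, modifiers, expr,
                          boundary)
    return net


def _add_reaction(net, tid, reactants, products, modifiers, expr, boundary):
    net.add_transition(Transition(tid, "continuous", expr))
    connected = set()
    for sid, stoich in reactants:
        if sid in boundary:
            net.add_arc(sid, tid, "modifier")
        else:
            net.add_arc(sid, tid, "standard", ex.Num(stoich))
        connected.add(sid)
    for sid, stoich in products:
        if sid in boundary:
            if sid not in connected:
                net.add_arc(sid, tid, "modifier")
        else:
            net.add_arc(tid, sid, "standard", ex.Num(stoich))
        connected.add(sid)
    for sid in modifiers:
        if sid not in connected:
            net.add_arc(sid, tid, "modifier")
    # rate references not yet connected become modifier arcs so the net
    # passes structural validation (SBML places no such constraint)
    for sid in sorted(ex.dependencies(expr) - connected
                      - {a.source for a in net.input_arcs(tid)}):
        net.add_arc(sid, tid, "modifier")


# ---------------------------------------------------------------------------
# Export
# ---------------------------------------------------------------------------

def export_sbml(net: HybridPetriNet | ColouredNet,
                regime_choice: str = "continuous") -> str:
    """Serialise the net as an SBML L2V4 document (string).

    SBML cannot carry a hybrid partition, so ``regime_choice`` states how
    the whole exported model is meant to be simulated (``"stochastic"`` or
    ``"continuous"``); it is recorded in the model notes.  Coloured nets
    are unfolded first.  ``MassAction`` rates are flattened into explicit
    products.  Timed transition kinds have no SBML counterpart.
    """
    if regime_choice not in ("stochastic", "continuous"):
        raise ValueError("regime_choice must be 'stochastic' or 'continuous'")
    if isinstance(net, ColouredNet):
        net = unfold(net)
    for t in net.transitions.values():
        if t.kind not in mdl.RATE_BEARING_KINDS:
            raise UnsupportedSbmlError(
                f"transition {t.id!r} of kind {t.kind!r} has no SBML "
                "representation")

    ET.register_namespace("", SBML_NS)
    root = ET.Element(_q("sbml"), {"level": "2", "version": "4"})
    model = ET.SubElement(root, _q("model"), {"id": net.name})
    notes = ET.SubElement(model, _q("notes"))
    body = ET.SubElement(notes, "{http://www.w3.org/1999/xhtml}p")
    body.text = f"regime: {regime_choice}"

    loc = ET.SubElement(model, _q("listOfCompartments"))
    ET.SubElement(loc, _q("compartment"), {"id": "cell", "size": "1"})

    los = ET.SubElement(model, _q("listOfSpecies"))
    for p in net.places.values():
        ET.SubElement(los, _q("species"), {
            "id": p.id, "compartment": "cell",
            "initialAmount": repr(float(p.initial_marking)),
            "hasOnlySubstanceUnits": "true"})

    if net.parameters:
        lop = ET.SubElement(model, _q("listOfParameters"))
        for k in sorted(net.parameters):
            ET.SubElement(lop, _q("parameter"),
                          {"id": k, "value": repr(float(net.parameters[k]))})

    lor = ET.SubElement(model, _q("listOfReactions"))
    for t in net.transitions.values():
        rx = ET.SubElement(lor, _q("reaction"),
                           {"id": t.id, "reversible": "false"})
        reactants, modifiers = [], []
        for a in net.input_arcs(t.id):
            w = ex.constant_value(a.weight)
            if a.kind == "standard":
                if w is None:
                    raise UnsupportedSbmlError(
                        f"arc {a.source!r} -> {t.id!r}: SBML stoichiometry "
                        "must be constant")
                reactants.append((a.source, w))
            else:
                modifiers.append(a.source)
        products = []
        for a in net.output_arcs(t.id):
            if a.kind == "standard":
                w = ex.constant_value(a.weight)
                if w is None:
                    raise UnsupportedSbmlError(
                        f"arc {t.id!r} -> {a.target!r}: SBML stoichiometry "
                        "must be constant")
                products.append((a.target, w))
        if reactants:
            lst = ET.SubElement(rx, _q("listOfReactants"))
            for sid, w in reactants:
                ET.SubElement(lst, _q("speciesReference"),
                              {"species": sid, "stoichiometry": repr(float(w))})
        if products:
            lst = ET.SubElement(rx, _q("listOfProducts"))
            for sid, w in products:
                ET.SubElement(lst, _q("speciesReference"),
                              {"species": sid, "stoichiometry": repr(float(w))})
        seen = set()
        mods = [m for m in modifiers if not (m in seen or seen.add(m))]
        if mods:
            lst = ET.SubElement(rx, _q("listOfModifiers"))
            for sid in mods:
                ET.SubElement(lst, _q("modifierSpeciesReference"),
                              {"species": sid})
        klaw = ET.SubElement(rx, _q("kineticLaw"))
        math = ET.SubElement(klaw, _q("math", MATHML_NS))
        math.append(_expr_to_mathml(net.expanded_rate(t.id)))

    ET.indent(root)
    return ('<?xml version="1.0" encoding="UTF-8"?>\n'
            + ET.tostring(root, encoding="unicode") + "\n")
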