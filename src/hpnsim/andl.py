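"""Plain-text model format (an ANDL-style dialect).

A human-readable, round-trip-stable notation for hybrid and coloured hybrid
Petri nets, compatible in spirit with the abstract net description
languages used by Petri net analysis tools (the exact grammars of which are
unpublished); the full grammar with examples ships in ``docs/andl.md``.

Layout sketch::

    hybrid net NAME
    constants:
      k = 0.5;
    places:
      discrete:
        close = 1;
      continuous:
        Ca = 0;
    transitions:
      stochastic:
        ch_open:
          [close - 1] [open + 1]
          rate: MassAction(k);

Arc markers: ``-`` standard input, ``+`` standard output, ``?`` read,
``!`` inhibitor, ``=`` equal, ``0`` reset, ``~`` modifier.  The coloured
dialect adds ``colorsets:``/``variables:`` sections, ``name : CS = m;``
place declarations (with optional per-colour overrides in braces),
``vars:`` and ``guard:`` clauses, and arc colour expressions in braces,
e.g. ``[Ca{x, y} - 1]`` or ``[open{all} ~ 1]``.
"""

from __future__ import annotations

import re
from typing import Mapping

from . import expressions as ex
from .coloured import (ALL, ColouredNet, IntRange, ProductSet, flat_name)
from .model import (ARC_KINDS, HybridPetriNet, Place, Transition,
                    TRANSITION_KINDS)

__all__ = ["AndlError", "parse_andl", "write_andl"]

_MARKER_TO_KIND = {"-": "standard_in", "+": "standard_out", "?": "read",
                   "!": "inhibitor", "=": "equal", "0": "reset",
                   "~": "modifier"}
_KIND_TO_MARKER = {"standard_in": "-", "standard_out": "+", "read": "?",
                   "inhibitor": "!", "equal": "=", "reset": "0",
                   "modifier": "~"}

_SECTIONS = ("constants", "colorsets", "variables", "places", "transitions")
_PLACE_SUBS = ("discrete", "continuous")

_HEADER_RE = re.compile(r"^(coloured\s+)?hybrid\s+net\s+([A-Za-z_]\w*)$")
_ARC_RE = re.compile(r"\[([^\]]*)\]")
_ARC_BODY_RE = re.compile(
    r"^\s*([A-Za-z_][\w.]*)\s*(\{[^}]*\})?\s*([-+?!=0~])\s*(.*?)\s*$")


class AndlError(Exception):
    def __init__(self, message: str, line: int | None = None):
        where = f"line {line}: " if line else ""
        super().__init__(f"{where}{message}")
        self.line = line


def _fmt_num(v: float) -> str:
    return str(int(v)) if v == int(v) and abs(v) < 1e16 else repr(float(v))


# ---------------------------------------------------------------------------
# Parsing
# ---------------------------------------------------------------------------

def _lines(text: str):
    for i, raw in enumerate(text.splitlines(), start=1):
        line = raw.split("#", 1)[0].rstrip()
        if line.strip():
            yield i, line.strip()


def parse_andl(text: str) -> HybridPetriNet | ColouredNet:
    """Parse a document; returns a coloured net iff it declares colour sets."""
    lines = list(_lines(text))
    if not lines:
        raise AndlError("empty document")
    ln, header = lines[0]
    m = _HEADER_RE.match(header)
    if not m:
        raise AndlError(f"expected 'hybrid net NAME' header, got {header!r}", ln)
    name = m.group(2)

    section = None
    subsection = None
    constants: dict[str, float] = {}
    colorsets: dict[str, object] = {}
    raw_colorsets: list[tuple[int, str]] = []
    variables: dict[str, str] = {}  # var -> colour-set name
    raw_places: list[tuple[int, str, str]] = []   # (line, subsection, stmt)
    raw_transitions: list[dict] = []
    current_t: dict | None = None

    for ln, line in lines[1:]:
        if line.rstrip(":") in _SECTIONS and line.endswith(":") \
                and " " not in line:
            section = line.rstrip(":")
            subsection = None
            current_t = None
            continue
        if section in ("places", "transitions"):
            bare = line.rstrip(":")
            if line.endswith(":") and bare in (
                    _PLACE_SUBS if section == "places" else TRANSITION_KINDS):
                subsection = bare
                current_t = None
                continue
        if section == "constants":
            m = re.match(r"^([A-Za-z_][\w.]*)\s*=\s*(\S+)\s*;$", line)
            if not m:
                raise AndlError(f"bad constant statement {line!r}", ln)
            constants[m.group(1)] = float(m.group(2))
        elif section == "colorsets":
            raw_colorsets.append((ln, line))
        elif section == "variables":
            m = re.match(r"^([A-Za-z_]\w*)\s*:\s*([A-Za-z_]\w*)\s*;$", line)
            if not m:
                raise AndlError(f"bad variable declaration {line!r}", ln)
            variables[m.group(1)] = m.group(2)
        elif section == "places":
            if subsection is None:
                raise AndlError("place outside discrete:/continuous: block", ln)
            raw_places.append((ln, subsection, line))
        elif section == "transitions":
            if subsection is None:
                raise AndlError(f"transition content outside a kind block: "
                                f"{line!r}", ln)
            tm = re.match(r"^([A-Za-z_]\w*)\s*:$", line)
            if tm:
                current_t = {"id": tm.group(1), "kind": subsection,
                             "line": ln, "arcs": [], "clauses": {}}
                raw_transitions.append(current_t)
            elif line.startswith("["):
                if current_t is None:
                    raise AndlError("arc line before any transition", ln)
                for arc_body in _ARC_RE.findall(line):
                    current_t["arcs"].append((ln, arc_body))
                rest = _ARC_RE.sub("", line).strip()
                if rest:
                    raise AndlError(f"unexpected text beside arcs: {rest!r}", ln)
            else:
                cm = re.match(r"^(rate|guard|delay|schedule|weight|hint|vars)"
                              r"\s*:\s*(.*);$", line) \
                    or re.match(r"^(combinatorial)()\s*;$", line)
                if not cm or current_t is None:
                    raise AndlError(f"unrecognised statement {line!r}", ln)
                current_t["clauses"][cm.group(1)] = (ln, cm.group(2).strip())
        elif section is None:
            raise AndlError(f"statement before any section: {line!r}", ln)
        else:  # pragma: no cover - defensive
            raise AndlError(f"unrecognised statement {line!r}", ln)

    for ln, line in raw_colorsets:
        m = re.match(r"^([A-Za-z_]\w*)\s*=\s*\[\s*(-?\d+)\s*\.\.\s*(-?\d+)\s*\]\s*;$",
                     line)
        if m:
            colorsets[m.group(1)] = IntRange(m.group(1), int(m.group(2)),
                                             int(m.group(3)))
            continue
        m = re.match(r"^([A-Za-z_]\w*)\s*=\s*([A-Za-z_]\w*(?:\s*x\s*[A-Za-z_]\w*)+)\s*;$",
                     line)
        if m:
            factors = []
            for fname in re.split(r"\s*x\s*", m.group(2)):
                if fname not in colorsets or \
                        not isinstance(colorsets[fname], IntRange):
                    raise AndlError(f"unknown range colour set {fname!r}", ln)
                factors.append(colorsets[fname])
            colorsets[m.group(1)] = ProductSet(m.group(1), tuple(factors))
            continue
        raise AndlError(f"bad colour set declaration {line!r}", ln)

    if colorsets or variables:
        return _build_coloured(name, constants, colorsets, variables,
                               raw_places, raw_transitions)
    return _build_flat(name, constants, raw_places, raw_transitions)


def _parse_expr(text: str, symbols: ex.SymbolTable, ln: int) -> ex.Expression:
    try:
        return ex.parse_expression(text, symbols)
    except ex.ParseError as err:
        raise AndlError(f"in expression {text!r}: {err}", ln) from err


def _parse_arc(ln: int, body: str, coloured: bool):
    m = _ARC_BODY_RE.match(body)
    if not m:
        raise AndlError(f"bad arc {body!r}", ln)
    place, colour_raw, marker, weight_raw = m.groups()
    if colour_raw and not coloured:
        raise AndlError(f"colour expression on arc of a flat net: {body!r}", ln)
    kind = _MARKER_TO_KIND[marker]
    return place, colour_raw, kind, (weight_raw or "1")


def _build_flat(name, constants, raw_places, raw_transitions) -> HybridPetriNet:
    net = HybridPetriNet(name, constants)
    for ln, sub, line in raw_places:
        m = re.match(r"^([A-Za-z_][\w.]*)\s*=\s*(\S+)\s*;$", line)
        if not m:
            raise AndlError(f"bad place declaration {line!r}", ln)
        net.add_place(Place(m.group(1), sub, float(m.group(2))))
    sym = net.symbols()
    for t in raw_transitions:
        tid, kind, ln = t["id"], t["kind"], t["line"]
        cl = t["clauses"]
        kwargs = {}
        if "rate" in cl:
            kwargs["rate"] = _parse_expr(cl["rate"][1], sym, cl["rate"][0])
        if "delay" in cl:
            kwargs["delay"] = float(cl["delay"][1])
        if "weight" in cl:
            kwargs["weight"] = float(cl["weight"][1])
        if "hint" in cl:
            kwargs["partition_hint"] = cl["hint"][1]
        if "combinatorial" in cl:
            kwargs["combinatorial"] = True
        if "schedule" in cl:
            sm = re.match(r"^\(\s*(\S+)\s*,\s*(\S+)\s*,\s*(\S+)\s*\)$",
                          cl["schedule"][1])
            if not sm:
                raise AndlError(f"bad schedule {cl['schedule'][1]!r}",
                                cl["schedule"][0])
            kwargs["schedule"] = tuple(float(g) for g in sm.groups())
        net.add_transition(Transition(tid, kind, **kwargs))
        for aln, body in t["arcs"]:
            place, _, akind, weight_raw = _parse_arc(aln, body, coloured=False)
            if place not in net.places:
                raise AndlError(f"arc references unknown place {place!r}", aln)
            weight = _parse_expr(weight_raw, sym, aln)
            if akind == "standard_out":
                net.add_arc(tid, place, "standard", weight)
            elif akind == "standard_in":
                net.add_arc(place, tid, "standard", weight)
            else:
                net.add_arc(place, tid, akind, weight)
    return net


def _build_coloured(name, constants, colorsets, variables, raw_places,
                    raw_transitions) -> ColouredNet:
    cnet = ColouredNet(name, constants)
    for cs in colorsets.values():
        cnet.add_colour_set(cs)
    var_sets: dict[str, IntRange] = {}
    for vname, csname in variables.items():
        cs = colorsets.get(csname)
        if not isinstance(cs, IntRange):
            raise AndlError(f"variable {vname!r}: colour set {csname!r} must "
                            "be an integer range")
        var_sets[vname] = cs

    place_decl = re.compile(
        r"^([A-Za-z_][\w.]*)\s*:\s*([A-Za-z_]\w*)\s*=\s*(\S+?)\s*"
        r"(\{.*\})?\s*;$")
    for ln, sub, line in raw_places:
        m = place_decl.match(line)
        if not m:
            raise AndlError(f"bad coloured place declaration {line!r}", ln)
        pid, csname, init, over_raw = m.groups()
        if csname not in colorsets:
            raise AndlError(f"unknown colour set {csname!r}", ln)
        overrides = {}
        if over_raw:
            for key_raw, val_raw in re.findall(
                    r"(\(\s*-?\d+(?:\s*,\s*-?\d+)*\s*\)|-?\d+)\s*=\s*([^\s{}]+)",
                    over_raw):
                if key_raw.startswith("("):
                    key = tuple(int(c) for c in re.findall(r"-?\d+", key_raw))
                else:
                    key = int(key_raw)
                overrides[key] = float(val_raw)
        cnet.add_place(Place(pid, sub, float(init)), colorsets[csname],
                       marking_overrides=overrides)

    base_places = frozenset(cnet.places)
    for t in raw_transitions:
        tid, kind, ln = t["id"], t["kind"], t["line"]
        cl = t["clauses"]
        tvars: dict[str, IntRange] = {}
        if "vars" in cl:
            for vname in re.split(r"\s*,\s*", cl["vars"][1]):
                if vname not in var_sets:
                    raise AndlError(f"undeclared variable {vname!r}",
                                    cl["vars"][0])
                tvars[vname] = var_sets[vname]
        sym = ex.SymbolTable.make(base_places, constants, tvars)
        kwargs = {}
        if "rate" in cl:
            kwargs["rate"] = _parse_expr(cl["rate"][1], sym, cl["rate"][0])
        if "delay" in cl:
            kwargs["delay"] = float(cl["delay"][1])
        if "weight" in cl:
            kwargs["weight"] = float(cl["weight"][1])
        if "hint" in cl:
            kwargs["partition_hint"] = cl["hint"][1]
        if "combinatorial" in cl:
            kwargs["combinatorial"] = True
        if "schedule" in cl:
            sm = re.match(r"^\(\s*(\S+)\s*,\s*(\S+)\s*,\s*(\S+)\s*\)$",
                          cl["schedule"][1])
            if not sm:
                raise AndlError(f"bad schedule {cl['schedule'][1]!r}",
                                cl["schedule"][0])
            kwargs["schedule"] = tuple(float(g) for g in sm.groups())
        guard = None
        if "guard" in cl:
            guard = _parse_expr(cl["guard"][1], sym, cl["guard"][0])
        cnet.add_transition(Transition(tid, kind, **kwargs),
                            variables=tvars, guard=guard)
        for aln, body in t["arcs"]:
            place, colour_raw, akind, weight_raw = _parse_arc(aln, body, True)
            if place not in cnet.places:
                raise AndlError(f"arc references unknown place {place!r}", aln)
            weight = _parse_expr(weight_raw, sym, aln)
            if colour_raw is None:
                raise AndlError(f"coloured arc needs a colour expression: "
                                f"{body!r}", aln)
            inner = colour_raw.strip()[1:-1].strip()
            if inner == ALL:
                colour = ALL
            else:
                colour = tuple(_parse_expr(c.strip(), sym, aln)
                               for c in inner.split(","))
            direction = "out" if akind == "standard_out" else "in"
            kind_final = "standard" if akind.startswith("standard") else akind
            cnet.add_arc(place, tid, direction, kind_final, weight, colour)
    return cnet


# ---------------------------------------------------------------------------
# Writing (canonical form)
# ---------------------------------------------------------------------------

def write_andl(net: HybridPetriNet | ColouredNet) -> str:
    """Canonical text rendering; ``parse_andl(write_andl(n)) == n``."""
    if isinstance(net, ColouredNet):
        return _write_coloured(net)
    return _write_flat(net)


def _transition_clauses(t: Transition, indent: str) -> list[str]:
    out = []
    if t.rate is not None:
        out.append(f"{indent}rate: {ex.to_text(t.rate)};")
    if t.delay is not None:
        out.append(f"{indent}delay: {_fmt_num(t.delay)};")
    if t.schedule is not None:
        s = ", ".join(_fmt_num(v) for v in t.schedule)
        out.append(f"{indent}schedule: ({s});")
    if t.weight is not None:
        out.append(f"{indent}weight: {_fmt_num(t.weight)};")
    if t.partition_hint is not None:
        out.append(f"{indent}hint: {t.partition_hint};")
    if t.combinatorial:
        out.append(f"{indent}combinatorial;")
    return out


def _write_flat(net: HybridPetriNet) -> str:
    out = [f"hybrid net {net.name}", ""]
    if net.parameters:
        out.append("constants:")
        for k in sorted(net.parameters):
            out.append(f"  {k} = {_fmt_num(net.parameters[k])};")
        out.append("")
    out.append("places:")
    for sub in _PLACE_SUBS:
        ps = sorted((p for p in net.places.values() if p.kind == sub),
                    key=lambda p: p.id)
        if ps:
            out.append(f"  {sub}:")
            for p in ps:
                out.append(f"    {p.id} = {_fmt_num(p.initial_marking)};")
    out.append("")
    out.append("transitions:")
    for kind in TRANSITION_KINDS:
        ts = sorted((t for t in net.transitions.values() if t.kind == kind),
                    key=lambda t: t.id)
        if not ts:
            continue
        out.append(f"  {kind}:")
        for t in ts:
            out.append(f"    {t.id}:")
            arcs = []
            for a in sorted(net.input_arcs(t.id),
                            key=lambda a: (a.source, a.kind)):
                marker = _KIND_TO_MARKER[
                    "standard_in" if a.kind == "standard" else a.kind]
                arcs.append(f"[{a.source} {marker} {ex.to_text(a.weight)}]")
            for a in sorted(net.output_arcs(t.id),
                            key=lambda a: (a.target, a.kind)):
                marker = "+" if a.kind == "standard" else \
                    _KIND_TO_MARKER[a.kind]
                arcs.append(f"[{a.target} {marker} {ex.to_text(a.weight)}]")
            if arcs:
                out.append("      " + " ".join(arcs))
            out.extend(_transition_clauses(t, "      "))
    return "\n".join(out) + "\n"


def _colour_key_text(key) -> str:
    if isinstance(key, tuple):
        return "(" + ", ".join(str(c) for c in key) + ")"
    return str(key)


def _write_coloured(cnet: ColouredNet) -> str:
    out = [f"coloured hybrid net {cnet.name}", ""]
    if cnet.parameters:
        out.append("constants:")
        for k in sorted(cnet.parameters):
            out.append(f"  {k} = {_fmt_num(cnet.parameters[k])};")
        out.append("")
    out.append("colorsets:")
    ranges = [cs for cs in cnet.colour_sets.values()
              if isinstance(cs, IntRange)]
    products = [cs for cs in cnet.colour_sets.values()
                if isinstance(cs, ProductSet)]
    for cs in sorted(ranges, key=lambda c: c.name):
        out.append(f"  {cs.name} = [{cs.lo}..{cs.hi}];")
    for cs in sorted(products, key=lambda c: c.name):
        out.append(f"  {cs.name} = {' x '.join(f.name for f in cs.factors)};")
    out.append("")
    all_vars: dict[str, str] = {}
    for ct in cnet.transitions.values():
        for vname, vset in ct.variables.items():
            all_vars[vname] = vset.name
    if all_vars:
        out.append("variables:")
        for vname in sorted(all_vars):
            out.append(f"  {vname} : {all_vars[vname]};")
        out.append("")
    out.append("places:")
    for sub in _PLACE_SUBS:
        cps = sorted((cp for cp in cnet.places.values()
                      if cp.place.kind == sub), key=lambda cp: cp.place.id)
        if not cps:
            continue
        out.append(f"  {sub}:")
        for cp in cps:
            line = (f"    {cp.place.id} : {cp.colour_set.name} = "
                    f"{_fmt_num(cp.place.initial_marking)}")
            if cp.marking_overrides:
                items = " ".join(
                    f"{_colour_key_text(k)} = {_fmt_num(v)}"
                    for k, v in sorted(cp.marking_overrides.items()))
                line += " { " + items + " }"
            out.append(line + ";")
    out.append("")
    out.append("transitions:")
    for kind in TRANSITION_KINDS:
        cts = sorted((ct for ct in cnet.transitions.values()
                      if ct.transition.kind == kind),
                     key=lambda ct: ct.transition.id)
        if not cts:
            continue
        out.append(f"  {kind}:")
        for ct in cts:
            t = ct.transition
            out.append(f"    {t.id}:")
            if ct.variables:
                out.append(f"      vars: {', '.join(ct.variables)};")
            arcs = []
            for a in sorted(cnet.transition_arcs(t.id),
                            key=lambda a: (a.direction, a.place, a.kind)):
                if a.colour == ALL:
                    colour = "{all}"
                else:
                    colour = "{" + ", ".join(ex.to_text(c)
                                             for c in a.colour) + "}"
                marker = "+" if (a.direction == "out"
                                 and a.kind == "standard") else \
                    _KIND_TO_MARKER["standard_in" if a.kind == "standard"
                                    else a.kind]
                arcs.append(f"[{a.place}{colour} {marker} "
                            f"{ex.to_text(a.weight)}]")
            if arcs:
                out.append("      " + " ".join(arcs))
            if ct.guard is not None:
                out.append(f"      guard: {ex.to_text(ct.guard)};")
            out.extend(_transition_clauses(t, "      "))
    return "\n".join(out) + "\n"
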