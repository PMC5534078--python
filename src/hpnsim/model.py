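"""Hybrid Petri net data model.

A generalised hybrid Petri net (GHPN) is a bipartite graph of *places*
(species; discrete with integer token counts or continuous with real
markings), *transitions* (reactions; stochastic, continuous, immediate,
deterministically delayed or scheduled) and *arcs* (standard, read,
inhibitor, equal, reset, modifier).  Transition rates are kinetic rate-law
expressions over places and parameters ("bio-semantics": the modeller
supplies the rate law, e.g. mass action, and the same expression serves the
stochastic and the deterministic regime).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping

from . import expressions as ex
from .expressions import Expression

__all__ = [
    "Place", "Transition", "Arc", "HybridPetriNet", "Violation", "NetError",
    "PLACE_KINDS", "TRANSITION_KINDS", "ARC_KINDS", "RATE_BEARING_KINDS",
    "stoichiometry", "reset_places", "enabled", "validate",
]

PLACE_KINDS = ("discrete", "continuous")
TRANSITION_KINDS = ("stochastic", "continuous", "immediate",
                    "deterministic_delay", "scheduled")
ARC_KINDS = ("standard", "read", "inhibitor", "equal", "reset", "modifier")

#: transition kinds that carry a rate expression and take part in regime
#: partitioning
RATE_BEARING_KINDS = ("stochastic", "continuous")

#: arc kinds that change the marking when the transition fires
_MARKING_CHANGING = ("standard", "reset")

# relative slack used when clamping slightly negative continuous markings
# produced by integrator round-off; larger negatives are reported as errors
NEGATIVE_CLAMP_FACTOR = 10.0


class NetError(Exception):
    """Structural error raised eagerly by the add_* operations."""


@dataclass
class Place:
    id: str
    kind: str = "discrete"
    initial_marking: float = 0.0
    is_logical: bool = False

    def __post_init__(self):
        if self.kind not in PLACE_KINDS:
            raise NetError(f"unknown place kind {self.kind!r} for {self.id!r}")


@dataclass
class Transition:
    id: str
    kind: str = "stochastic"
    rate: Expression | None = None
    delay: float | None = None
    schedule: tuple | None = None  # (start, interval, end)
    weight: float | None = None    # immediate conflict weight
    partition_hint: str | None = None  # "stochastic" | "deterministic"
    combinatorial: bool = False    # use falling-factorial mass action

    def __post_init__(self):
        if self.kind not in TRANSITION_KINDS:
            raise NetError(f"unknown transition kind {self.kind!r} for {self.id!r}")
        if self.partition_hint not in (None, "stochastic", "deterministic"):
            raise NetError(f"bad partition_hint {self.partition_hint!r} "
                           f"for {self.id!r}")


@dataclass
class Arc:
    source: str
    target: str
    kind: str = "standard"
    weight: Expression = field(default_factory=lambda: ex.Num(1.0))

    def __post_init__(self):
        if self.kind not in ARC_KINDS:
            raise NetError(f"unknown arc kind {self.kind!r} "
                           f"({self.source} -> {self.target})")
        if isinstance(self.weight, (int, float)):
            self.weight = ex.Num(float(self.weight))


@dataclass(frozen=True)
class Violation:
    """A broken structural rule; data, not an exception."""

    rule: str
    nodes: tuple
    message: str


class HybridPetriNet:
    """The simulatable model: places, transitions, arcs and parameters."""

    def __init__(self, name: str = "net",
                 parameters: Mapping[str, float] | None = None):
        self.name = name
        self.places: dict[str, Place] = {}
        self.transitions: dict[str, Transition] = {}
        self.arcs: list[Arc] = []
        self.parameters: dict[str, float] = dict(parameters or {})
        self.views: dict[str, object] = {}
        # adjacency index: node id -> incoming/outgoing arcs (kept in sync by
        # add_arc so the structural queries stay O(degree) on large nets)
        self._in: dict[str, list] = {}
        self._out: dict[str, list] = {}

    # -- construction -------------------------------------------------------

    def add_place(self, place: Place | str, **kwargs) -> "HybridPetriNet":
        if isinstance(place, str):
            place = Place(place, **kwargs)
        if place.id in self.places or place.id in self.transitions:
            raise NetError(f"duplicate id {place.id!r}")
        self.places[place.id] = place
        return self

    def add_transition(self, transition: Transition | str, **kwargs) -> "HybridPetriNet":
        if isinstance(transition, str):
            transition = Transition(transition, **kwargs)
        if transition.id in self.transitions or transition.id in self.places:
            raise NetError(f"duplicate id {transition.id!r}")
        self.transitions[transition.id] = transition
        return self

    def add_arc(self, source: str, target: str, kind: str = "standard",
                weight: Expression | float = 1.0) -> "HybridPetriNet":
        src_is_place = source in self.places
        tgt_is_place = target in self.places
        if not (source in self.places or source in self.transitions):
            raise NetError(f"dangling arc endpoint {source!r}")
        if not (target in self.places or target in self.transitions):
            raise NetError(f"dangling arc endpoint {target!r}")
        if src_is_place == tgt_is_place:
            raise NetError(f"bipartite violation: arc {source!r} -> {target!r} "
                           "must connect one place and one transition")
        arc = Arc(source, target, kind, weight)
        self.arcs.append(arc)
        self._out.setdefault(source, []).append(arc)
        self._in.setdefault(target, []).append(arc)
        return self

    def set_parameter(self, name: str, value: float) -> "HybridPetriNet":
        self.parameters[name] = float(value)
        return self

    # -- queries -------------------------------------------------------------

    def symbols(self, variables: Iterable[str] = ()) -> ex.SymbolTable:
        return ex.SymbolTable.make(self.places, self.parameters, variables)

    def parse_rate(self, text: str) -> Expression:
        return ex.parse_expression(text, self.symbols())

    def input_arcs(self, transition_id: str) -> list[Arc]:
        """Arcs from places to the transition (any kind)."""
        return self._in.get(transition_id, [])

    def output_arcs(self, transition_id: str) -> list[Arc]:
        return self._out.get(transition_id, [])

    def place_arcs(self, place_id: str) -> list[Arc]:
        return self._in.get(place_id, []) + self._out.get(place_id, [])

    def initial_marking(self) -> dict[str, float]:
        return {p.id: p.initial_marking for p in self.places.values()}

    def writers(self, place_id: str) -> set[str]:
        """Transitions that change the place's marking (standard/reset arcs)."""
        out = set()
        for a in self.place_arcs(place_id):
            if a.kind in _MARKING_CHANGING:
                out.add(a.target if a.source == place_id else a.source)
        return out

    def expanded_rate(self, transition_id: str) -> Expression:
        """Rate with ``MassAction(k)`` expanded over the transition's inputs."""
        t = self.transitions[transition_id]
        if t.rate is None:
            raise NetError(f"transition {transition_id!r} has no rate")
        inputs = []
        for a in self.input_arcs(transition_id):
            if a.kind in ("standard", "read"):
                w = ex.constant_value(a.weight)
                if w is None:
                    raise NetError(
                        f"MassAction on {transition_id!r} requires constant "
                        f"arc weights ({a.source!r} is not)")
                inputs.append((a.source, w))
        return ex.expand_mass_action(t.rate, inputs)

    def __eq__(self, other) -> bool:
        if not isinstance(other, HybridPetriNet):
            return NotImplemented
        return (self.places == other.places
                and self.transitions == other.transitions
                and sorted(self.arcs, key=_arc_key) == sorted(other.arcs, key=_arc_key)
                and self.parameters == other.parameters)

    def __repr__(self) -> str:  # pragma: no cover
        return (f"<HybridPetriNet {self.name!r}: |P|={len(self.places)} "
                f"|T|={len(self.transitions)} |A|={len(self.arcs)}>")


def _arc_key(a: Arc):
    return (a.source, a.target, a.kind, ex.to_text(a.weight))


# ---------------------------------------------------------------------------
# Structural validation
# ---------------------------------------------------------------------------

def validate(net: HybridPetriNet) -> list[Violation]:
    """Check every structural invariant; returns the (sorted) violation list.

    Idempotent and insertion-order independent.  An empty list means the net
    is legal.
    """
    out: list[Violation] = []

    for p in net.places.values():
        if p.kind == "discrete":
            m = p.initial_marking
            if m != int(m) or m < 0:
                out.append(Violation(
                    "discrete_marking_integer", (p.id,),
                    f"discrete place {p.id!r} must hold a non-negative "
                    f"integer marking, got {m}"))
        elif p.initial_marking < 0:
            out.append(Violation(
                "continuous_marking_nonnegative", (p.id,),
                f"continuous place {p.id!r} has negative initial marking "
                f"{p.initial_marking}"))

    for t in net.transitions.values():
        if t.kind in RATE_BEARING_KINDS and t.rate is None:
            out.append(Violation("missing_rate", (t.id,),
                                 f"{t.kind} transition {t.id!r} has no rate"))
        if t.kind == "deterministic_delay" and (t.delay is None or t.delay < 0):
            out.append(Violation("bad_delay", (t.id,),
                                 f"transition {t.id!r} needs a non-negative delay"))
        if t.kind == "scheduled" and t.schedule is None:
            out.append(Violation("bad_schedule", (t.id,),
                                 f"transition {t.id!r} needs a schedule"))
        if t.kind == "immediate" and t.weight is not None and t.weight <= 0:
            out.append(Violation("bad_weight", (t.id,),
                                 f"immediate transition {t.id!r} needs a "
                                 "positive weight"))

    for a in net.arcs:
        pid = a.source if a.source in net.places else a.target
        tid = a.target if a.target in net.transitions else a.source
        place = net.places[pid]
        trans = net.transitions[tid]
        if a.kind in ("reset", "equal") and place.kind == "continuous":
            out.append(Violation(
                "reset_equal_on_continuous", (pid, tid),
                f"{a.kind} arc between {pid!r} and {tid!r}: reset/equal arcs "
                "are only defined for discrete places"))
        # continuous flow must not corrupt integer markings
        if (trans.kind == "continuous" and place.kind == "discrete"
                and a.kind in _MARKING_CHANGING):
            out.append(Violation(
                "continuous_writes_discrete", (pid, tid),
                f"continuous transition {tid!r} may touch discrete place "
                f"{pid!r} only via read/inhibitor/equal/modifier arcs"))

    # a species manipulated by both regimes must be continuous
    for p in net.places.values():
        if p.kind != "discrete":
            continue
        kinds = {net.transitions[t].kind for t in net.writers(p.id)}
        if "stochastic" in kinds and "continuous" in kinds:
            out.append(Violation(
                "both_regimes", (p.id,),
                f"place {p.id!r} is written by both a stochastic and a "
                "continuous transition and must therefore be continuous"))

    # every place referenced by a rate must be connected by some arc
    for t in net.transitions.values():
        if t.rate is None:
            continue
        try:
            deps = ex.dependencies(net.expanded_rate(t.id))
        except NetError:
            deps = ex.dependencies(t.rate)
        connected = {a.source for a in net.input_arcs(t.id)}
        connected |= {a.target for a in net.output_arcs(t.id)}
        for pid in sorted(deps - connected):
            out.append(Violation(
                "unconnected_rate_ref", (t.id, pid),
                f"rate of {t.id!r} reads {pid!r} which is not connected to "
                "the transition by any arc"))

    out.sort(key=lambda v: (v.rule, v.nodes))
    return out


# ---------------------------------------------------------------------------
# Stoichiometry and enabledness
# ---------------------------------------------------------------------------

def stoichiometry(net: HybridPetriNet, transition_id: str,
                  marking: Mapping[str, float] | None = None) -> dict[str, float]:
    """Signed marking change per place when the transition fires.

    Standard output arcs add their weight, standard input arcs subtract
    theirs; read/inhibitor/equal/modifier arcs contribute nothing.  Reset
    arcs are excluded here (see :func:`reset_places`).  Expression weights
    are evaluated at ``marking`` (default: the initial marking).  A
    non-integer net change on a discrete place is an error.
    """
    if marking is None:
        marking = net.initial_marking()
    delta: dict[str, float] = {}
    for a in net.input_arcs(transition_id):
        if a.kind == "standard":
            w = ex.evaluate(a.weight, marking, net.parameters, context=transition_id)
            delta[a.source] = delta.get(a.source, 0.0) - w
    for a in net.output_arcs(transition_id):
        if a.kind == "standard":
            w = ex.evaluate(a.weight, marking, net.parameters, context=transition_id)
            delta[a.target] = delta.get(a.target, 0.0) + w
    delta = {k: v for k, v in delta.items() if v != 0.0}
    for pid, v in delta.items():
        if net.places[pid].kind == "discrete" and v != int(v):
            raise NetError(
                f"transition {transition_id!r} changes discrete place "
                f"{pid!r} by the non-integer amount {v}")
    return delta


def reset_places(net: HybridPetriNet, transition_id: str) -> set[str]:
    """Places set to zero by reset arcs when the transition fires."""
    return {(a.source if a.source in net.places else a.target)
            for a in net.arcs
            if a.kind == "reset" and transition_id in (a.source, a.target)}


def enabled(net: HybridPetriNet, transition_id: str,
            marking: Mapping[str, float]) -> bool:
    """Token-based enabledness at ``marking``.

    standard/read input places must hold at least the arc weight, equal
    input places exactly the weight, inhibitor input places strictly less
    (so an inhibitor arc of weight *w* blocks once the place reaches *w*).
    Continuous transitions additionally require a strictly positive rate.
    """
    t = net.transitions[transition_id]
    for a in net.input_arcs(transition_id):
        w = ex.evaluate(a.weight, marking, net.parameters, context=transition_id)
        m = marking[a.source]
        if a.kind in ("standard", "read") and m < w:
            return False
        if a.kind == "equal" and m != w:
            return False
        if a.kind == "inhibitor" and m >= w:
            return False
    if t.kind == "continuous":
        rate = ex.evaluate(net.expanded_rate(transition_id), marking,
                           net.parameters, context=transition_id)
        if rate <= 0.0:
            return False
    return True
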