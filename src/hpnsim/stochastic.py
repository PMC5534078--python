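"""Discrete-event engine.

Propensity computation, the Gillespie direct method, the reaction
dependency graph (with the dependent/independent classification that drives
solver-reinitialisation avoidance), and the rejection-based (RSSA)
machinery: fluctuation intervals, propensity bounds and candidate
selection with the squeeze test.

Waiting times throughout are exponential: ``tau = -log(r) / a0`` with
``r ~ U(0,1)``; a candidate reaction ``j`` is selected in proportion to its
propensity by a linear cumulative-sum search.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np

from . import expressions as ex
from . import model as mdl
from .model import HybridPetriNet

__all__ = [
    "RandomStream", "PropensityState", "FluctuationInterval",
    "PropensityEvaluator", "compute_propensities", "direct_method_step",
    "build_dependency_graph", "classify_dependent",
    "make_fluctuation_interval", "propensity_bounds", "rssa_select",
    "BoundsExit", "NoStochasticEvent",
]


class NoStochasticEvent(Exception):
    """Signalled when the total propensity is zero: no event before the horizon."""


@dataclass(frozen=True)
class BoundsExit:
    """rssa_select outcome: the state left the fluctuation interval first."""

    time: float


class RandomStream:
    """Seeded uniform stream with a documented substream derivation.

    Substream ``i`` of seed ``s`` is ``PCG64(SeedSequence((s, i)))``; the
    same (seed, stream) pair yields the same draw sequence on every
    platform, which is what makes multi-worker ensembles bit-reproducible.
    Draws are uniform on the open interval (0, 1).
    """

    def __init__(self, seed: int, stream: int = 0):
        self.seed = int(seed)
        self.stream = int(stream)
        self._gen = np.random.Generator(
            np.random.PCG64(np.random.SeedSequence((self.seed, self.stream))))

    def uniform(self) -> float:
        u = self._gen.random()
        while u == 0.0:  # open interval: log(u) must be finite
            u = self._gen.random()
        return u

    def exponential(self, rate: float) -> float:
        return -math.log(self.uniform()) / rate

    def spawn(self, stream: int) -> "RandomStream":
        return RandomStream(self.seed, stream)


@dataclass
class PropensityState:
    """Per-stochastic-transition propensities and their total."""

    transition_ids: tuple
    a: np.ndarray
    a0: float = field(init=False)

    def __post_init__(self):
        self.a0 = float(np.sum(self.a))

    def refresh_total(self):
        self.a0 = float(np.sum(self.a))


class PropensityEvaluator:
    """Compiled propensity functions over a flat state vector.

    ``a_j(x) = rate_j(x)`` if transition j is token-enabled at ``x``, else 0.
    Tiny negative rate values (round-off from continuous inputs) are clamped
    to zero.  Arc weights on enabling arcs must be constants for the
    compiled path; expression weights fall back to tree-walk evaluation.
    """

    def __init__(self, net: HybridPetriNet, transition_ids: Sequence[str],
                 place_index: Mapping[str, int],
                 param_values: Mapping[str, float] | None = None):
        self.net = net
        self.transition_ids = tuple(transition_ids)
        self.place_index = dict(place_index)
        params = dict(net.parameters if param_values is None else param_values)
        self._param_names = sorted(params)
        self._pidx = {n: i for i, n in enumerate(self._param_names)}
        self.param_vec = np.array([params[n] for n in self._param_names], float)
        self._fns: list[Callable] = []
        self._conds: list[list[tuple[int, str, float]]] = []
        self._slow: list[tuple[str, ex.Expression] | None] = []
        for tid in self.transition_ids:
            expr = net.expanded_rate(tid)
            t = net.transitions[tid]
            if t.combinatorial:
                expr = _combinatorial_rate(net, tid, t.rate)
            self._fns.append(ex.compile_expression(expr, self.place_index, self._pidx))
            conds = []
            slow = None
            for a in net.input_arcs(tid):
                if a.kind == "modifier":
                    continue
                w = ex.constant_value(a.weight)
                if w is None:
                    slow = (tid, expr)
                    break
                conds.append((self.place_index[a.source], a.kind, w))
            self._conds.append(conds)
            self._slow.append(slow)

    def propensity(self, j: int, x: np.ndarray) -> float:
        if self._slow[j] is not None:
            tid = self.transition_ids[j]
            marking = {p: x[i] for p, i in self.place_index.items()}
            if not mdl.enabled(self.net, tid, marking):
                return 0.0
            val = ex.evaluate(self.net.expanded_rate(tid), marking,
                              self.net.parameters, context=tid)
            return val if val > 0.0 else 0.0
        for idx, kind, w in self._conds[j]:
            m = x[idx]
            if kind in ("standard", "read"):
                if m < w:
                    return 0.0
            elif kind == "equal":
                if m != w:
                    return 0.0
            elif kind == "inhibitor":
                if m >= w:
                    return 0.0
        val = self._fns[j](x, self.param_vec)
        if not math.isfinite(val):
            raise ex.EvaluationError(
                f"rate of {self.transition_ids[j]!r} is not finite")
        return val if val > 0.0 else 0.0

    def all_propensities(self, x: np.ndarray) -> np.ndarray:
        return np.array([self.propensity(j, x)
                         for j in range(len(self.transition_ids))], float)


def _combinatorial_rate(net: HybridPetriNet, tid: str,
                        rate: ex.Expression) -> ex.Expression:
    """Falling-factorial mass action ``k * prod C(x_i, w_i) * w_i!``-free form.

    Expands ``MassAction(k)`` to ``k * prod x(x-1)...(x-w+1) / w!`` for
    exact-CME use on discrete inputs (the plain product is the default).
    """
    if not (isinstance(rate, ex.Call) and rate.func == "MassAction"):
        raise mdl.NetError(
            f"combinatorial flag on {tid!r} requires a MassAction rate")
    k = rate.args[0]
    node: ex.Expression = k
    for a in sorted(net.input_arcs(tid), key=lambda a: a.source):
        if a.kind not in ("standard", "read"):
            continue
        w = ex.constant_value(a.weight)
        if w is None or w != int(w):
            raise mdl.NetError(
                f"combinatorial MassAction on {tid!r} needs constant integer "
                f"arc weights")
        w = int(w)
        for i in range(w):
            factor: ex.Expression = ex.Ref(a.source, "place")
            if i:
                factor = ex.BinOp("-", factor, ex.Num(float(i)))
            node = ex.BinOp("*", node, factor)
        node = ex.BinOp("/", node, ex.Num(float(math.factorial(w))))
    return node


# ---------------------------------------------------------------------------
# Direct method
# ---------------------------------------------------------------------------

def compute_propensities(net: HybridPetriNet, marking: Mapping[str, float],
                         stochastic_set: Iterable[str]) -> PropensityState:
    """Propensity vector over ``stochastic_set`` at ``marking``."""
    tids = tuple(sorted(stochastic_set))
    a = np.zeros(len(tids))
    for j, tid in enumerate(tids):
        if mdl.enabled(net, tid, marking):
            val = ex.evaluate(net.expanded_rate(tid), marking, net.parameters,
                              context=tid)
            a[j] = val if val > 0.0 else 0.0
    return PropensityState(tids, a)


def direct_method_step(ps: PropensityState, rng: RandomStream) -> tuple[int, float]:
    """One Gillespie direct-method draw: (reaction index, waiting time).

    ``tau = -log(r1)/a0``; ``j`` is the smallest index whose cumulative
    propensity reaches ``r2 * a0``.  Raises :class:`NoStochasticEvent` when
    ``a0`` is zero (the caller then integrates to the horizon).
    """
    if ps.a0 <= 0.0:
        raise NoStochasticEvent
    tau = -math.log(rng.uniform()) / ps.a0
    j = select_index(ps.a, ps.a0, rng.uniform())
    return j, tau


def select_index(a: np.ndarray, a0: float, r: float) -> int:
    """Smallest j with ``sum(a[:j+1]) >= r * a0`` (linear cumulative search)."""
    target = r * a0
    acc = 0.0
    for j in range(len(a)):
        acc += a[j]
        if acc >= target:
            return j
    return len(a) - 1  # guard against round-off in the final sum


# ---------------------------------------------------------------------------
# Dependency graph
# ---------------------------------------------------------------------------

def _changed_places(net: HybridPetriNet, tid: str) -> set[str]:
    return set(mdl.stoichiometry(net, tid)) | mdl.reset_places(net, tid)


def _listens_to(net: HybridPetriNet, tid: str) -> set[str]:
    """Places whose marking can alter transition ``tid``'s propensity:
    rate dependencies plus every enabling (non-modifier) input place."""
    deps = ex.dependencies(net.expanded_rate(tid))
    deps |= {a.source for a in net.input_arcs(tid) if a.kind != "modifier"}
    return deps


def build_dependency_graph(net: HybridPetriNet, partition) -> dict:
    """``graph[j] = {k : firing j may change a_k}`` over the stochastic set.

    Also used for the dependent/independent classification, see
    :func:`classify_dependent`.
    """
    stoch = sorted(partition.stochastic_set)
    listens = {k: _listens_to(net, k) for k in stoch}
    graph: dict[str, set] = {}
    for j in stoch:
        changed = _changed_places(net, j)
        graph[j] = {k for k in stoch if listens[k] & changed}
    return graph


def classify_dependent(net: HybridPetriNet, partition) -> set[str]:
    """Stochastic reactions whose firing perturbs the deterministic regime.

    A reaction is DEPENDENT iff the places it changes intersect the
    continuous species or the dependencies of any deterministic rate; only
    dependent firings force an ODE-solver reinitialisation.
    """
    det_deps: set[str] = set()
    for tid in partition.deterministic_set:
        det_deps |= ex.dependencies(net.expanded_rate(tid))
    sensitive = set(partition.continuous_species) | det_deps
    return {j for j in partition.stochastic_set
            if _changed_places(net, j) & sensitive}


# ---------------------------------------------------------------------------
# RSSA machinery
# ---------------------------------------------------------------------------

@dataclass
class FluctuationInterval:
    """Per-species [lo, hi] brackets plus the propensity bounds they imply."""

    species: tuple
    lo: dict
    hi: dict
    a_low: np.ndarray = field(default_factory=lambda: np.zeros(0))
    a_high: np.ndarray = field(default_factory=lambda: np.zeros(0))

    @property
    def a_high_total(self) -> float:
        return float(np.sum(self.a_high))

    def contains(self, marking: Mapping[str, float]) -> bool:
        return all(self.lo[s] <= marking[s] <= self.hi[s] for s in self.species)

    def interval_marking(self, marking: Mapping[str, float]) -> dict:
        out = {s: (self.lo[s], self.hi[s]) for s in self.species}
        for pid, v in marking.items():
            if pid not in out:
                out[pid] = (v, v)
        return out


def make_fluctuation_interval(net: HybridPetriNet,
                              marking: Mapping[str, float],
                              species: Iterable[str],
                              delta: float = 0.1,
                              floor: float = 2.0) -> FluctuationInterval:
    """Bracket each tracked species by ``[x(1-delta), x(1+delta)]``.

    Discrete species are widened to at least ``x -/+ floor`` so that a few
    firings do not immediately invalidate the bounds; continuous species
    near zero are widened to at least ``x -/+ delta`` so the interval never
    degenerates to a point (which would trigger an exit on any motion).
    Lower bounds are clamped at zero.
    """
    if not 0.0 < delta < 1.0:
        raise ValueError(f"delta must lie in (0, 1), got {delta}")
    species = tuple(sorted(species))
    lo, hi = {}, {}
    for s in species:
        x = float(marking[s])
        l, h = x * (1.0 - delta), x * (1.0 + delta)
        if net.places[s].kind == "discrete":
            l = min(l, x - floor)
            h = max(h, x + floor)
        else:
            l = min(l, x - delta)
            h = max(h, x + delta)
        lo[s] = max(0.0, l)
        hi[s] = h
    return FluctuationInterval(species, lo, hi)


def propensity_bounds(net: HybridPetriNet, fi: FluctuationInterval,
                      transition_ids: Sequence[str],
                      marking: Mapping[str, float]) -> FluctuationInterval:
    """Fill ``fi`` with per-reaction propensity bounds over its intervals.

    The rate expression is bounded by interval arithmetic; enabledness over
    the interval is resolved in tri-state: definitely enabled everywhere
    keeps the rate's lower bound, possibly disabled forces the lower bound
    to 0, definitely disabled zeroes both bounds.
    """
    iv = fi.interval_marking(marking)
    n = len(transition_ids)
    a_low = np.zeros(n)
    a_high = np.zeros(n)
    for j, tid in enumerate(transition_ids):
        definitely, possibly = _interval_enabled(net, tid, iv)
        if not possibly:
            continue
        lo, hi = ex.bounds(net.expanded_rate(tid), iv, net.parameters)
        lo, hi = max(lo, 0.0), max(hi, 0.0)
        a_low[j] = lo if definitely else 0.0
        a_high[j] = hi
    fi.a_low = a_low
    fi.a_high = a_high
    return fi


def _interval_enabled(net: HybridPetriNet, tid: str, iv: Mapping[str, tuple]):
    """(definitely enabled everywhere, possibly enabled somewhere)."""
    definitely, possibly = True, True
    for a in net.input_arcs(tid):
        if a.kind == "modifier":
            continue
        w = ex.constant_value(a.weight)
        if w is None:
            definitely = False
            continue
        lo, hi = iv[a.source]
        if a.kind in ("standard", "read"):
            if hi < w:
                return False, False
            if lo < w:
                definitely = False
        elif a.kind == "equal":
            if hi < w or lo > w:
                return False, False
            if not (lo == hi == w):
                definitely = False
        elif a.kind == "inhibitor":
            if lo >= w:
                return False, False
            if hi >= w:
                definitely = False
    return definitely, possibly


def rssa_select(net: HybridPetriNet, fi: FluctuationInterval,
                transition_ids: Sequence[str],
                marking_provider: Callable[[float], Mapping[str, float] | BoundsExit],
                rng: RandomStream, t0: float = 0.0):
    """Rejection-based selection of the next firing.

    Candidate times arrive as a Poisson process of rate ``sum(a_high)``;
    the candidate reaction is drawn proportionally to its upper bound and
    accepted with probability ``a_j(x(t)) / a_high_j`` (auto-accepted by the
    squeeze test when ``u * a_high_j <= a_low_j``).  Rejection draws a fresh
    candidate time and continues.  Returns ``(j, t_fire)`` with ``j`` an
    index into ``transition_ids``, or a :class:`BoundsExit` if the provider
    reports a state outside the interval first.  Raises
    :class:`NoStochasticEvent` when all upper bounds vanish.
    """
    ahigh0 = fi.a_high_total
    if ahigh0 <= 0.0:
        raise NoStochasticEvent
    t = t0
    while True:
        t = t + rng.exponential(ahigh0)
        state = marking_provider(t)
        if isinstance(state, BoundsExit):
            return state
        j = select_index(fi.a_high, ahigh0, rng.uniform())
        u = rng.uniform()
        if u * fi.a_high[j] <= fi.a_low[j]:
            return j, t
        aj = _exact_propensity(net, transition_ids[j], state)
        if u * fi.a_high[j] <= aj:
            return j, t


def _exact_propensity(net: HybridPetriNet, tid: str,
                      marking: Mapping[str, float]) -> float:
    if not mdl.enabled(net, tid, marking):
        return 0.0
    val = ex.evaluate(net.expanded_rate(tid), marking, net.parameters, context=tid)
    return val if val > 0.0 else 0.0
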