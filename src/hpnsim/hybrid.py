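"""Hybrid synchronisation algorithms and the ensemble runner.

Implemented algorithms (``SimulationConfig.algorithm``):

``hr_exact``
    Exact jump-equation hybrid: a fresh uniform r is drawn per span and the
    ODE system is augmented with the accumulator ``dg/dt = sum_j a_j^s(x(t))``
    over the slow propensities; the next stochastic firing happens at the
    root of ``g + log(r) = 0``, the firing reaction is selected with
    probability proportional to its propensity *at the event time*, and the
    solver is reinitialised after every firing.

``accelerated``
    The waiting time is closed-form, ``dt = -log(r) / sum_j a_j^s(x)`` with
    propensities frozen at the last event; the ODEs are integrated to
    ``t + dt`` without a root function, and the solver is reinitialised only
    when the fired reaction is *dependent* (changes state the deterministic
    regime reads).  Exact whenever slow propensities do not read continuous
    species, an approximation otherwise.

``hrssa``
    Hybrid rejection-based simulation: per-species fluctuation intervals
    give propensity lower/upper bounds; candidate firings arrive at the
    upper-bound rate and are accepted against the exact state (squeeze test
    first), so control returns to the stochastic regime only at candidate
    times or when the state leaves its fluctuation interval.  Combines the
    rejection machinery with the accelerated reinitialisation rule.

``dynamic``
    The hrssa loop with state-driven repartitioning: every fluctuation-
    interval exit re-applies the propensity/substrate partitioning
    thresholds, rebuilding the ODE system when any class changes.

``pure_ssa`` / ``pure_ode``
    All reactions stochastic (Gillespie direct method) or all deterministic
    (one ODE system), ignoring any partition.

All algorithms share the timed-transition machinery (immediate >
scheduled/delayed > stochastic at equal times, ties broken by id) and a
fixed uniform output grid so ensembles can be averaged pointwise.
"""

from __future__ import annotations

import math
from concurrent.futures import ProcessPoolExecutor
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np

from . import expressions as ex
from . import model as mdl
from . import stochastic as st
from .model import HybridPetriNet, RATE_BEARING_KINDS
from .ode import Integrator, IntegratorConfig, OdeSystem, build_ode_system
from .stochastic import (NoStochasticEvent, PropensityEvaluator, RandomStream,
                         select_index)

__all__ = [
    "Partition", "SimulationConfig", "Trace", "TimedScheduler",
    "make_partition", "dynamic_partition", "run_simulation",
    "hr_exact_run", "accelerated_run", "hrssa_run", "dynamic_run",
    "pure_ssa_run", "pure_ode_run", "run_ensemble", "ALGORITHMS",
]

ALGORITHMS = ("hr_exact", "accelerated", "hrssa", "dynamic",
              "pure_ssa", "pure_ode")

_EPS = 1e-12
_MAX_IMMEDIATE = 10_000


# ---------------------------------------------------------------------------
# Partition
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Partition:
    """Assignment of rate-bearing transitions to regimes.

    Species classes are derived: a species is continuous iff it is declared
    continuous or is written by any deterministic transition (a species
    manipulated by both regimes must be continuous), so discrete species are
    written only by the stochastic regime.
    """

    stochastic_set: frozenset
    deterministic_set: frozenset
    continuous_species: frozenset
    discrete_species: frozenset


def make_partition(net: HybridPetriNet,
                   stochastic: Iterable[str] | None = None,
                   deterministic: Iterable[str] | None = None) -> Partition:
    """Build (and check) a partition; defaults follow transition kinds.

    ``partition_hint`` on a transition overrides its kind-based default.
    """
    rate_bearing = {t.id for t in net.transitions.values()
                    if t.kind in RATE_BEARING_KINDS}
    if stochastic is None and deterministic is None:
        stoch, det = set(), set()
        for tid in rate_bearing:
            t = net.transitions[tid]
            regime = t.partition_hint or (
                "stochastic" if t.kind == "stochastic" else "deterministic")
            (stoch if regime == "stochastic" else det).add(tid)
    else:
        stoch = set(stochastic or ())
        det = set(deterministic if deterministic is not None
                  else rate_bearing - stoch)
    if stoch & det:
        raise ValueError(f"regimes overlap: {sorted(stoch & det)}")
    if (stoch | det) != rate_bearing:
        missing = rate_bearing - (stoch | det)
        extra = (stoch | det) - rate_bearing
        raise ValueError(
            f"partition must cover exactly the rate-bearing transitions "
            f"(missing {sorted(missing)}, extraneous {sorted(extra)})")
    return _derive_classes(net, stoch, det)


def _derive_classes(net: HybridPetriNet, stoch: set, det: set) -> Partition:
    continuous = {p.id for p in net.places.values() if p.kind == "continuous"}
    for tid in det:
        continuous |= set(mdl.stoichiometry(net, tid))
        continuous |= mdl.reset_places(net, tid)
    discrete = set(net.places) - continuous
    return Partition(frozenset(stoch), frozenset(det),
                     frozenset(continuous), frozenset(discrete))


def dynamic_partition(net: HybridPetriNet, marking: Mapping[str, float],
                      lambda_prop: float, n_substrate: float) -> Partition:
    """State-driven partitioning.

    A rate-bearing transition goes deterministic iff its current propensity
    is at least ``lambda_prop`` AND every substrate (standard/read input
    place) holds at least ``n_substrate``; otherwise it stays stochastic.
    Transitions carrying a ``partition_hint`` are pinned to it.
    """
    if lambda_prop < 0 or n_substrate < 0:
        raise ValueError("thresholds must be non-negative")
    stoch, det = set(), set()
    for t in net.transitions.values():
        if t.kind not in RATE_BEARING_KINDS:
            continue
        if t.partition_hint is not None:
            (stoch if t.partition_hint == "stochastic" else det).add(t.id)
            continue
        a = 0.0
        if mdl.enabled(net, t.id, marking):
            a = max(0.0, ex.evaluate(net.expanded_rate(t.id), marking,
                                     net.parameters, context=t.id))
        substrates = {arc.source for arc in net.input_arcs(t.id)
                      if arc.kind in ("standard", "read")}
        fast = a >= lambda_prop and all(
            marking[p] >= n_substrate for p in substrates)
        (det if fast else stoch).add(t.id)
    return _derive_classes(net, stoch, det)


# ---------------------------------------------------------------------------
# Configuration and traces
# ---------------------------------------------------------------------------

@dataclass
class SimulationConfig:
    algorithm: str = "hrssa"
    t_start: float = 0.0
    t_end: float = 10.0
    output_points: int = 1000
    output_grid: np.ndarray | None = None
    seed: int = 0
    runs: int = 1
    workers: int = 1
    integrator: IntegratorConfig = field(default_factory=IntegratorConfig)
    delta: float = 0.1        # fluctuation-interval half width (relative)
    floor: float = 2.0        # minimum absolute widening for discrete species
    lambda_prop: float = 10.0   # dynamic partitioning: propensity threshold
    n_substrate: float = 100.0  # dynamic partitioning: substrate threshold
    record: tuple | None = None  # place/transition ids; default: all places

    def __post_init__(self):
        if self.algorithm not in ALGORITHMS:
            raise ValueError(f"unknown algorithm {self.algorithm!r}; "
                             f"choose from {ALGORITHMS}")
        if self.t_end <= self.t_start:
            raise ValueError("t_end must exceed t_start")
        if self.runs < 1:
            raise ValueError("runs must be at least 1")

    def grid(self) -> np.ndarray:
        if self.output_grid is not None:
            return np.asarray(self.output_grid, float)
        return np.linspace(self.t_start, self.t_end, self.output_points)


@dataclass
class Trace:
    """Time-ordered record of selected node values on the output grid."""

    times: np.ndarray
    columns: tuple
    values: np.ndarray  # shape (len(times), len(columns))
    meta: dict = field(default_factory=dict)

    def column(self, node_id: str) -> np.ndarray:
        return self.values[:, self.columns.index(node_id)]

    def to_dataframe(self):
        import pandas as pd
        return pd.DataFrame(self.values, index=pd.Index(self.times, name="time"),
                            columns=list(self.columns))


# ---------------------------------------------------------------------------
# Timed transitions (immediate / deterministic delay / scheduled)
# ---------------------------------------------------------------------------

class TimedScheduler:
    """Time-ordered event queue for the non-rate-bearing transition kinds.

    Scheduled transitions fire at ``start, start+interval, ..., <= end``
    (one firing when the interval is zero).  A delay transition is booked
    ``delay`` after it becomes enabled at a span boundary and cancelled if
    found disabled at a later boundary before it fires.  Immediate
    transitions fire first at any time point, repeatedly until quiescence,
    with probabilistic conflict resolution proportional to their weights.
    """

    def __init__(self, net: HybridPetriNet, t_start: float, t_end: float):
        self.net = net
        self.immediates = sorted(t.id for t in net.transitions.values()
                                 if t.kind == "immediate")
        self.queue: list[tuple[float, str]] = []
        self._delay_booked: dict[str, float | None] = {
            t.id: None for t in net.transitions.values()
            if t.kind == "deterministic_delay"}
        for t in net.transitions.values():
            if t.kind == "scheduled":
                start, interval, end = t.schedule
                tq = start
                while tq <= min(end, t_end) + _EPS:
                    if tq >= t_start - _EPS:
                        self.queue.append((tq, t.id))
                    if interval <= 0:
                        break
                    tq += interval
        self.queue.sort()

    def update_delays(self, t: float, marking: Mapping[str, float]) -> None:
        for tid, booked in self._delay_booked.items():
            is_enabled = mdl.enabled(self.net, tid, marking)
            if is_enabled and booked is None:
                due = t + self.net.transitions[tid].delay
                self._delay_booked[tid] = due
                self.queue.append((due, tid))
                self.queue.sort()
            elif not is_enabled and booked is not None:
                self.queue.remove((booked, tid))
                self._delay_booked[tid] = None

    def next_time(self) -> float:
        return self.queue[0][0] if self.queue else math.inf

    def pop_due(self, t: float) -> list[str]:
        """Due (time, id)-ordered firing candidates at time ``t``."""
        fired = []
        while self.queue and self.queue[0][0] <= t + _EPS:
            _, tid = self.queue.pop(0)
            if tid in self._delay_booked:
                self._delay_booked[tid] = None
            fired.append(tid)
        return fired


# ---------------------------------------------------------------------------
# Engine
# ---------------------------------------------------------------------------

class _Recorder:
    def __init__(self, grid: np.ndarray, columns: Sequence[str]):
        self.times = grid
        self.columns = tuple(columns)
        self.values = np.empty((len(grid), len(columns)))
        self.pos = 0

    def fill_to(self, t_upper: float, sampler) -> None:
        while self.pos < len(self.times) and self.times[self.pos] <= t_upper + _EPS:
            self.values[self.pos] = sampler(self.times[self.pos])
            self.pos += 1


class _Engine:
    """Shared state and mechanics for one simulation run."""

    def __init__(self, net: HybridPetriNet, partition: Partition,
                 config: SimulationConfig, rng: RandomStream):
        violations = mdl.validate(net)
        if violations:
            raise mdl.NetError(
                "net fails validation: "
                + "; ".join(v.message for v in violations))
        self.net = net
        self.partition = partition
        self.config = config
        self.rng = rng
        self.place_index = {p: i for i, p in enumerate(net.places)}
        self.x = np.array([net.places[p].initial_marking
                           for p in net.places], float)
        self.slow_ids: tuple = tuple(sorted(partition.stochastic_set))
        self.slow = PropensityEvaluator(net, self.slow_ids, self.place_index)
        self.dependent = st.classify_dependent(net, partition)
        self.dep_graph = st.build_dependency_graph(net, partition)
        self._slow_pos = {tid: j for j, tid in enumerate(self.slow_ids)}
        self.system: OdeSystem | None = None
        self.integ: Integrator | None = None
        if partition.continuous_species:
            self.system = build_ode_system(net, partition)
            self.integ = Integrator(self.system, config.integrator,
                                    y0=self.x[np.array(
                                        [self.place_index[s]
                                         for s in self.system.species], int)],
                                    t0=config.t_start)
        self.scheduler = TimedScheduler(net, config.t_start, config.t_end)
        self._stoich_cache: dict[str, tuple] = {}
        self.n_events = 0
        self.reinit_extra = 0  # reinitialisations outside the Integrator
        self.event_times: list[float] = []
        self.event_ids: list[str] = []
        columns = tuple(config.record) if config.record else tuple(net.places)
        for c in columns:
            if c not in net.places and c not in net.transitions:
                raise ValueError(f"unknown recorded node {c!r}")
        self.fire_counts = {tid: 0 for tid in net.transitions}
        self.rec = _Recorder(config.grid(), columns)
        self._col_place = [self.place_index.get(c) for c in columns]
        self._cont_pos = {}
        if self.system is not None:
            sp_pos = {s: k for k, s in enumerate(self.system.species)}
            for ci, c in enumerate(columns):
                if c in sp_pos:
                    self._cont_pos[ci] = sp_pos[c]

    # -- state access -------------------------------------------------------

    def marking(self) -> dict:
        return {p: self.x[i] for p, i in self.place_index.items()}

    def sync_continuous(self, y: np.ndarray) -> None:
        if self.system is not None:
            self.x[self.system.cont_idx] = y[:self.system.dim]

    # -- firing -------------------------------------------------------------

    def _stoich(self, tid: str):
        cached = self._stoich_cache.get(tid)
        if cached is not None:
            return cached
        arcs = self.net.input_arcs(tid) + self.net.output_arcs(tid)
        constant = all(ex.constant_value(a.weight) is not None
                       for a in arcs if a.kind == "standard")
        delta = mdl.stoichiometry(self.net, tid, self.marking())
        idx = np.array([self.place_index[p] for p in sorted(delta)], int)
        dv = np.array([delta[p] for p in sorted(delta)], float)
        resets = np.array([self.place_index[p]
                           for p in sorted(mdl.reset_places(self.net, tid))], int)
        entry = (idx, dv, resets)
        if constant:
            self._stoich_cache[tid] = entry
        return entry

    def fire(self, tid: str) -> np.ndarray:
        """Apply the transition's stoichiometry; returns changed indices."""
        idx, dv, resets = self._stoich(tid)
        self.x[idx] += dv
        if len(resets):
            self.x[resets] = 0.0
        self.fire_counts[tid] += 1
        if (self.x[idx] < 0).any():
            bad = idx[self.x[idx] < 0][0]
            pid = list(self.place_index)[bad]
            raise mdl.NetError(
                f"firing {tid!r} drove place {pid!r} negative "
                f"({self.x[bad]})")
        return np.concatenate([idx, resets]) if len(resets) else idx

    def record_event(self, t: float, tid: str) -> None:
        self.n_events += 1
        self.event_times.append(t)
        self.event_ids.append(tid)

    # -- timed transitions --------------------------------------------------

    def run_immediates(self, t: float) -> bool:
        """Fire enabled immediate transitions to quiescence; True if any fired."""
        if not self.scheduler.immediates:
            return False
        fired_any = False
        for _ in range(_MAX_IMMEDIATE):
            m = self.marking()
            candidates = [tid for tid in self.scheduler.immediates
                          if mdl.enabled(self.net, tid, m)]
            if not candidates:
                return fired_any
            weights = np.array([self.net.transitions[tid].weight or 1.0
                                for tid in candidates])
            j = select_index(weights, float(weights.sum()), self.rng.uniform())
            self.fire(candidates[j])
            fired_any = True
        raise mdl.NetError(
            f"immediate transitions did not quiesce within {_MAX_IMMEDIATE} "
            f"firings at t={t}")

    def boundary(self, t: float) -> bool:
        """Immediates-then-delay bookkeeping at a span boundary."""
        fired = self.run_immediates(t)
        self.scheduler.update_delays(t, self.marking())
        return fired

    def process_timed(self, t: float) -> bool:
        """Fire due scheduled/delayed transitions at time ``t``."""
        fired_any = self.run_immediates(t)
        for tid in self.scheduler.pop_due(t):
            if mdl.enabled(self.net, tid, self.marking()):
                self.fire(tid)
                fired_any = True
                self.run_immediates(t)
        self.scheduler.update_delays(t, self.marking())
        return fired_any

    # -- recording ----------------------------------------------------------

    def sampler(self, sol=None):
        """Row sampler over the recorded columns for the current span."""
        def sample(tq: float) -> np.ndarray:
            y = sol(tq) if sol is not None else None
            row = np.empty(len(self.rec.columns))
            for ci, col in enumerate(self.rec.columns):
                pi = self._col_place[ci]
                if pi is None:  # transition column: cumulative firing count
                    row[ci] = self.fire_counts[col]
                elif y is not None and ci in self._cont_pos:
                    row[ci] = y[self._cont_pos[ci]]
                else:
                    row[ci] = self.x[pi]
            return row
        return sample

    def finish(self, algorithm: str, run_id: int) -> Trace:
        self.rec.fill_to(self.config.t_end, self.sampler())
        reinits = (self.integ.reinit_count if self.integ else 0) + self.reinit_extra
        meta = {
            "algorithm": algorithm,
            "seed": self.rng.seed,
            "run_id": run_id,
            "n_events": self.n_events,
            "reinit_count": reinits,
            "event_times": np.array(self.event_times),
            "event_ids": tuple(self.event_ids),
            "stochastic_set": self.slow_ids,
            "continuous_species": tuple(sorted(self.partition.continuous_species)),
        }
        return Trace(self.rec.times.copy(), self.rec.columns,
                     self.rec.values.copy(), meta)


# ---------------------------------------------------------------------------
# Pure stochastic loop (also the zero-ODE fast path of the hybrid methods)
# ---------------------------------------------------------------------------

def _ssa_loop(eng: _Engine) -> None:
    """Gillespie direct method over ``eng.slow_ids``.

    Identical draw discipline to the jump-equation loop (one uniform for
    the waiting time, then one for the selection), so that on nets without
    continuous coupling the exact hybrid algorithms replay the same event
    sequence from the same stream.
    """
    cfg, rng = eng.config, eng.rng
    t = cfg.t_start
    eng.boundary(t)
    a = eng.slow.all_propensities(eng.x)
    while t < cfg.t_end:
        a0 = float(a.sum())
        t_timed = eng.scheduler.next_time()
        t_next = t - math.log(rng.uniform()) / a0 if a0 > 0.0 else math.inf
        if min(t_next, t_timed) > cfg.t_end:
            break
        if t_timed <= t_next:
            eng.rec.fill_to(t_timed, eng.sampler())
            t = t_timed
            eng.process_timed(t)
            a = eng.slow.all_propensities(eng.x)
            continue
        eng.rec.fill_to(t_next, eng.sampler())
        t = t_next
        j = select_index(a, a0, rng.uniform())
        tid = eng.slow_ids[j]
        eng.fire(tid)
        eng.record_event(t, tid)
        if eng.boundary(t):
            a = eng.slow.all_propensities(eng.x)
        else:
            for k in eng.dep_graph[tid]:
                kj = eng._slow_pos[k]
                a[kj] = eng.slow.propensity(kj, eng.x)


def pure_ssa_run(net: HybridPetriNet, config: SimulationConfig,
                 rng: RandomStream | None = None, run_id: int = 0) -> Trace:
    """Direct-method SSA over *all* rate-bearing transitions."""
    for p in net.places.values():
        if p.initial_marking != int(p.initial_marking):
            raise mdl.NetError(
                f"pure stochastic simulation requires integer markings; "
                f"place {p.id!r} holds {p.initial_marking} (marking not integer)")
    rate_bearing = {t.id for t in net.transitions.values()
                    if t.kind in RATE_BEARING_KINDS}
    partition = Partition(frozenset(rate_bearing), frozenset(),
                          frozenset(), frozenset(net.places))
    rng = rng or RandomStream(config.seed, run_id)
    eng = _Engine(net, partition, config, rng)
    _ssa_loop(eng)
    return eng.finish("pure_ssa", run_id)


def _ode_loop(eng: _Engine) -> None:
    """Span-wise deterministic integration (no stochastic regime), broken
    only by timed-transition firings."""
    cfg = eng.config
    t = cfg.t_start
    rhs = eng.system.make_rhs(eng.x)
    eng.boundary(t)
    while t < cfg.t_end:
        t1 = min(cfg.t_end, eng.scheduler.next_time())
        if t1 > t:
            res = eng.integ.integrate(rhs, t1)
            eng.rec.fill_to(res.t_stop, eng.sampler(res.segment))
            eng.sync_continuous(eng.integ.y)
            t = res.t_stop
        if t < cfg.t_end and eng.process_timed(t):
            eng.integ.reinitialise(eng.x[eng.system.cont_idx], t)
        elif t >= cfg.t_end:
            break
        else:
            eng.scheduler.pop_due(t)  # drop skipped (disabled) timed firings


def pure_ode_run(net: HybridPetriNet, config: SimulationConfig,
                 rng: RandomStream | None = None, run_id: int = 0) -> Trace:
    """One ODE system over all rate-bearing transitions; every species is
    treated as continuous."""
    rate_bearing = {t.id for t in net.transitions.values()
                    if t.kind in RATE_BEARING_KINDS}
    partition = Partition(frozenset(), frozenset(rate_bearing),
                          frozenset(net.places), frozenset())
    rng = rng or RandomStream(config.seed, run_id)
    eng = _Engine(net, partition, config, rng)
    _ode_loop(eng)
    return eng.finish("pure_ode", run_id)


# ---------------------------------------------------------------------------
# Exact jump-equation hybrid (Haseltine & Rawlings style)
# ---------------------------------------------------------------------------

def hr_exact_run(net: HybridPetriNet, partition: Partition | None,
                 config: SimulationConfig, rng: RandomStream | None = None,
                 run_id: int = 0) -> Trace:
    rng = rng or RandomStream(config.seed, run_id)
    partition = partition or make_partition(net)
    eng = _Engine(net, partition, config, rng)
    if eng.system is None or eng.system.dim == 0:
        # no continuous species: the jump integrand is piecewise constant and
        # the jump equation collapses to the direct method's exponential
        _ssa_loop(eng)
        tr = eng.finish("hr_exact", run_id)
        tr.meta["reinit_count"] = tr.meta["n_events"]
        return tr
    if not eng.slow_ids:
        # degenerate partition: no jump equation to augment, plain ODE spans
        _ode_loop(eng)
        return eng.finish("hr_exact", run_id)

    cfg = config
    slow = eng.slow

    def slow_total(template: np.ndarray) -> float:
        return sum(slow.propensity(j, template)
                   for j in range(len(eng.slow_ids)))

    rhs = eng.system.make_rhs(eng.x, aux=slow_total)
    # integrator state is the augmented vector [y, g]
    eng.integ.y = np.append(eng.integ.y, 0.0)
    t = cfg.t_start
    eng.boundary(t)
    target = -math.log(rng.uniform())
    while t < cfg.t_end:
        t1 = min(cfg.t_end, eng.scheduler.next_time())

        def jump_event(tt, yy, target=target):
            return yy[-1] - target
        jump_event.direction = 1
        res = eng.integ.integrate(rhs, t1, events=[jump_event])
        eng.rec.fill_to(res.t_stop, eng.sampler(res.segment))
        eng.sync_continuous(eng.integ.y)
        t = res.t_stop
        if res.reason == "event":
            a = np.array([slow.propensity(j, eng.x)
                          for j in range(len(eng.slow_ids))])
            a0 = float(a.sum())
            j = select_index(a, a0, rng.uniform())
            tid = eng.slow_ids[j]
            eng.fire(tid)
            eng.record_event(t, tid)
            eng.boundary(t)
            eng.integ.reinitialise(
                np.append(eng.x[eng.system.cont_idx], 0.0), t)
            target = -math.log(rng.uniform())
        elif t < cfg.t_end:
            g_now = eng.integ.y[-1]
            if eng.process_timed(t):
                # the jump integral g and its target survive timed firings
                eng.integ.reinitialise(
                    np.append(eng.x[eng.system.cont_idx], g_now), t)
    return eng.finish("hr_exact", run_id)


# ---------------------------------------------------------------------------
# Accelerated hybrid
# ---------------------------------------------------------------------------

def accelerated_run(net: HybridPetriNet, partition: Partition | None,
                    config: SimulationConfig, rng: RandomStream | None = None,
                    run_id: int = 0) -> Trace:
    rng = rng or RandomStream(config.seed, run_id)
    partition = partition or make_partition(net)
    eng = _Engine(net, partition, config, rng)
    if eng.system is None or eng.system.dim == 0:
        _ssa_loop(eng)
        tr = eng.finish("accelerated", run_id)
        tr.meta["reinit_count"] = 0
        return tr

    cfg = config
    rhs = eng.system.make_rhs(eng.x)
    t = cfg.t_start
    eng.boundary(t)
    while t < cfg.t_end:
        a = eng.slow.all_propensities(eng.x)  # frozen at the last event
        a0 = float(a.sum())
        r = rng.uniform()
        t_fire = t - math.log(r) / a0 if a0 > 0.0 else math.inf
        t1 = min(t_fire, cfg.t_end, eng.scheduler.next_time())
        if t1 > t:
            res = eng.integ.integrate(rhs, t1)
            eng.rec.fill_to(res.t_stop, eng.sampler(res.segment))
            eng.sync_continuous(eng.integ.y)
            t = res.t_stop
        if t + _EPS >= t_fire and t_fire <= cfg.t_end:
            j = select_index(a, a0, rng.uniform())
            tid = eng.slow_ids[j]
            eng.fire(tid)
            eng.record_event(t, tid)
            eng.boundary(t)
            if tid in eng.dependent:
                eng.integ.reinitialise(eng.x[eng.system.cont_idx], t)
        elif t < cfg.t_end:
            if eng.process_timed(t):
                eng.integ.reinitialise(eng.x[eng.system.cont_idx], t)
    return eng.finish("accelerated", run_id)


# ---------------------------------------------------------------------------
# Improved hybrid rejection-based simulation (and dynamic repartitioning)
# ---------------------------------------------------------------------------

def _fi_support(eng: _Engine, everything: bool = False) -> tuple:
    if everything:
        return tuple(sorted(eng.net.places))
    support: set = set()
    for tid in eng.slow_ids:
        support |= st._listens_to(eng.net, tid)
    return tuple(sorted(support))


def _hrssa_loop(eng: _Engine, repartition=None) -> None:
    """The hrssa core; with ``repartition`` it becomes the dynamic algorithm.

    ``repartition(eng, t)`` is called at every fluctuation-interval exit and
    returns True when any regime or species class changed (the caller then
    works with the rebuilt engine attributes).
    """
    cfg, rng, net = eng.config, eng.rng, eng.net
    track_all = repartition is not None
    support = _fi_support(eng, everything=track_all)

    def rebuild_interval():
        fi = st.make_fluctuation_interval(net, eng.marking(), support,
                                          cfg.delta, cfg.floor)
        return st.propensity_bounds(net, fi, eng.slow_ids, eng.marking())

    def exit_events(fi):
        evs = []
        if eng.system is None:
            return evs
        sp_pos = {s: k for k, s in enumerate(eng.system.species)}
        for s in fi.species:
            if s not in sp_pos:
                continue
            k = sp_pos[s]

            def up(tt, yy, k=k, hi=fi.hi[s]):
                return yy[k] - hi
            up.direction = 1

            def down(tt, yy, k=k, lo=fi.lo[s]):
                return yy[k] - lo
            down.direction = -1
            evs.append(up)
            if fi.lo[s] > 0.0:
                evs.append(down)
        return evs

    t = cfg.t_start
    eng.boundary(t)
    fi = rebuild_interval()
    evs = exit_events(fi)
    while t < cfg.t_end:
        ahigh0 = fi.a_high_total
        t_cand = t + rng.exponential(ahigh0) if ahigh0 > 0.0 else math.inf
        t1 = min(t_cand, cfg.t_end, eng.scheduler.next_time())
        if eng.system is not None and eng.system.dim > 0 and t1 > t:
            rhs = eng.system.make_rhs(eng.x)
            res = eng.integ.integrate(rhs, t1, events=evs)
            eng.rec.fill_to(res.t_stop, eng.sampler(res.segment))
            eng.sync_continuous(eng.integ.y)
            t = res.t_stop
            if res.reason == "event":  # fluctuation-interval exit
                if repartition is not None and repartition(eng, t):
                    support = _fi_support(eng, everything=track_all)
                fi = rebuild_interval()
                evs = exit_events(fi)
                continue
        else:
            eng.rec.fill_to(min(t1, cfg.t_end), eng.sampler())
            t = t1
        if t + _EPS >= t_cand and t_cand <= cfg.t_end:
            j = select_index(fi.a_high, ahigh0, rng.uniform())
            u = rng.uniform()
            accept = u * fi.a_high[j] <= fi.a_low[j]
            if not accept:
                aj = eng.slow.propensity(j, eng.x)
                accept = u * fi.a_high[j] <= aj
            if accept:
                tid = eng.slow_ids[j]
                eng.fire(tid)
                eng.record_event(t, tid)
                eng.boundary(t)
                if tid in eng.dependent and eng.system is not None \
                        and eng.system.dim > 0:
                    eng.integ.reinitialise(eng.x[eng.system.cont_idx], t)
                if not fi.contains(eng.marking()):
                    if repartition is not None and repartition(eng, t):
                        support = _fi_support(eng, everything=track_all)
                    fi = rebuild_interval()
                    evs = exit_events(fi)
        elif t < cfg.t_end and t + _EPS >= eng.scheduler.next_time():
            if eng.process_timed(t):
                if eng.system is not None and eng.system.dim > 0:
                    eng.integ.reinitialise(eng.x[eng.system.cont_idx], t)
                fi = rebuild_interval()
                evs = exit_events(fi)


def hrssa_run(net: HybridPetriNet, partition: Partition | None,
              config: SimulationConfig, rng: RandomStream | None = None,
              run_id: int = 0) -> Trace:
    rng = rng or RandomStream(config.seed, run_id)
    partition = partition or make_partition(net)
    eng = _Engine(net, partition, config, rng)
    _hrssa_loop(eng)
    return eng.finish("hrssa", run_id)


def _apply_partition(eng: _Engine, partition: Partition, t: float) -> None:
    """Swap the engine onto a new partition (dynamic repartitioning)."""
    old = eng.partition
    # species reverting from continuous to discrete class are rounded back
    # onto the integer lattice
    for s in sorted(old.continuous_species - partition.continuous_species):
        i = eng.place_index[s]
        eng.x[i] = float(round(eng.x[i]))
    eng.partition = partition
    eng.slow_ids = tuple(sorted(partition.stochastic_set))
    eng.slow = PropensityEvaluator(eng.net, eng.slow_ids, eng.place_index)
    eng._slow_pos = {tid: j for j, tid in enumerate(eng.slow_ids)}
    eng.dependent = st.classify_dependent(eng.net, partition)
    eng.dep_graph = st.build_dependency_graph(eng.net, partition)
    old_count = eng.integ.reinit_count if eng.integ else 0
    if partition.continuous_species:
        eng.system = build_ode_system(eng.net, partition)
        eng.integ = Integrator(eng.system, eng.config.integrator,
                               y0=eng.x[eng.system.cont_idx], t0=t)
        eng.integ.reinit_count = old_count + 1
        sp_pos = {s: k for k, s in enumerate(eng.system.species)}
        eng._cont_pos = {ci: sp_pos[c]
                         for ci, c in enumerate(eng.rec.columns) if c in sp_pos}
    else:
        eng.reinit_extra = old_count + 1
        eng.system = None
        eng.integ = None
        eng._cont_pos = {}


def dynamic_run(net: HybridPetriNet, config: SimulationConfig,
                rng: RandomStream | None = None, run_id: int = 0) -> Trace:
    """Dynamically partitioned hybrid simulation.

    Starts from the thresholds-based partition of the initial state and
    re-applies it at every fluctuation-interval exit; a repartition that
    changes any class rebuilds the ODE system and reinitialises.
    """
    rng = rng or RandomStream(config.seed, run_id)
    part0 = dynamic_partition(net, {p.id: p.initial_marking
                                    for p in net.places.values()},
                              config.lambda_prop, config.n_substrate)
    eng = _Engine(net, part0, config, rng)
    eng.meta_partition_changes = 0

    def repartition(e: _Engine, t: float) -> bool:
        new = dynamic_partition(e.net, e.marking(),
                                e.config.lambda_prop, e.config.n_substrate)
        if new == e.partition:
            return False
        _apply_partition(e, new, t)
        eng.meta_partition_changes += 1
        return True

    _hrssa_loop(eng, repartition=repartition)
    tr = eng.finish("dynamic", run_id)
    tr.meta["partition_changes"] = eng.meta_partition_changes
    return tr


# ---------------------------------------------------------------------------
# Dispatch and ensembles
# ---------------------------------------------------------------------------

def run_simulation(net: HybridPetriNet, config: SimulationConfig,
                   partition: Partition | None = None,
                   rng: RandomStream | None = None, run_id: int = 0) -> Trace:
    alg = config.algorithm
    if alg == "hr_exact":
        return hr_exact_run(net, partition, config, rng, run_id)
    if alg == "accelerated":
        return accelerated_run(net, partition, config, rng, run_id)
    if alg == "hrssa":
        return hrssa_run(net, partition, config, rng, run_id)
    if alg == "dynamic":
        return dynamic_run(net, config, rng, run_id)
    if alg == "pure_ssa":
        return pure_ssa_run(net, config, rng, run_id)
    return pure_ode_run(net, config, rng, run_id)


def _run_one(args) -> Trace:
    net, config, partition, run_id = args
    rng = RandomStream(config.seed, run_id)
    return run_simulation(net, config, partition, rng, run_id)


def run_ensemble(net: HybridPetriNet, config: SimulationConfig,
                 partition: Partition | None = None) -> tuple[Trace, list]:
    """Run ``config.runs`` independent runs and average them pointwise.

    Run ``i`` uses the substream ``(seed, i)``, so the result is
    bit-identical for any ``workers`` count; with ``workers > 1`` runs
    execute in a process pool.
    """
    jobs = [(net, config, partition, i) for i in range(config.runs)]
    if config.workers > 1 and config.runs > 1:
        with ProcessPoolExecutor(max_workers=config.workers) as pool:
            traces = list(pool.map(_run_one, jobs,
                                   chunksize=max(1, config.runs
                                                 // (4 * config.workers))))
    else:
        traces = [_run_one(j) for j in jobs]
    stack = np.stack([tr.values for tr in traces])
    avg = Trace(traces[0].times.copy(), traces[0].columns,
                stack.mean(axis=0),
                {"algorithm": config.algorithm, "seed": config.seed,
                 "runs": config.runs, "averaged": True,
                 "n_events": sum(tr.meta["n_events"] for tr in traces),
                 "reinit_count": sum(tr.meta["reinit_count"] for tr in traces)})
    return avg, traces
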