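"""Deterministic engine.

Builds the ODE system of the deterministic regime —
``dy_i/dt = sum_k s_ik * v_k(y, frozen discrete marking)`` over the
deterministic transitions k with stoichiometry s and kinetic rate v — and
integrates it with adaptive stepping, dense output and root (event)
detection via :func:`scipy.integrate.solve_ivp`.

Discrete markings enter the right-hand side as constants frozen for one
integration span; any discrete firing ends the span.  The integrator
front-end keeps a reinitialisation counter: discarding solver history after
a jump is exactly the cost the accelerated and rejection-based hybrid
algorithms avoid for independent firings, so the counter is the observable
tests (and the methods note) reason about.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
from scipy.integrate import solve_ivp

from . import expressions as ex
from . import model as mdl
from .model import HybridPetriNet

__all__ = ["IntegratorConfig", "OdeSystem", "Integrator", "IntegrationResult",
           "SolverFailure", "build_ode_system"]

_METHODS = {"stiff": "BDF", "nonstiff": "RK45"}


class SolverFailure(Exception):
    def __init__(self, message: str, t: float, y: np.ndarray):
        super().__init__(f"{message} (at t={t})")
        self.t = t
        self.y = y


@dataclass
class IntegratorConfig:
    method: str = "stiff"
    rtol: float = 1e-6
    atol: float = 1e-9
    max_step: float = math.inf
    root_tol: float = 1e-9

    def __post_init__(self):
        if self.method not in _METHODS:
            raise ValueError(f"method must be one of {sorted(_METHODS)}")
        if self.rtol <= 0 or self.atol <= 0:
            raise ValueError("tolerances must be positive")


class OdeSystem:
    """Continuous species order plus a compiled, side-effect-free rhs.

    The rhs reads a full-state template vector: continuous slots are
    overwritten from ``y`` on every call, discrete slots hold the frozen
    marking the caller maintains.  An optional auxiliary accumulator (the
    jump-equation integrand, the summed slow propensities) can be appended
    as one extra state entry.
    """

    def __init__(self, net: HybridPetriNet, species: Sequence[str],
                 det_transitions: Sequence[str],
                 place_index: Mapping[str, int]):
        self.net = net
        self.species = tuple(species)
        self.det_transitions = tuple(det_transitions)
        self.place_index = dict(place_index)
        self.cont_idx = np.array([self.place_index[s] for s in self.species],
                                 int)
        pnames = sorted(net.parameters)
        pidx = {n: i for i, n in enumerate(pnames)}
        self.param_vec = np.array([net.parameters[n] for n in pnames], float)
        self._rate_fns: list[Callable] = []
        n_sp, n_tr = len(self.species), len(self.det_transitions)
        self.stoich = np.zeros((n_sp, n_tr))
        sp_pos = {s: i for i, s in enumerate(self.species)}
        for k, tid in enumerate(self.det_transitions):
            expr = net.expanded_rate(tid)
            self._rate_fns.append(ex.compile_expression(expr, self.place_index,
                                                        pidx))
            for pid, dv in mdl.stoichiometry(net, tid).items():
                if pid not in sp_pos:
                    raise mdl.NetError(
                        f"deterministic transition {tid!r} writes {pid!r} "
                        "which is not classed continuous")
                self.stoich[sp_pos[pid], k] = dv

    @property
    def dim(self) -> int:
        return len(self.species)

    def rates(self, template: np.ndarray) -> np.ndarray:
        c = self.param_vec
        return np.array([f(template, c) for f in self._rate_fns])

    def make_rhs(self, template: np.ndarray,
                 aux: Callable[[np.ndarray], float] | None = None) -> Callable:
        """rhs(t, y) closing over the live full-state ``template``.

        With ``aux`` given, the state gains one trailing entry ``g`` with
        ``dg/dt = aux(template)`` (the accumulated slow-propensity integral
        of the exact jump equation).
        """
        cont = self.cont_idx
        stoich = self.stoich
        rate_fns = self._rate_fns
        c = self.param_vec

        if aux is None:
            def rhs(t, y):
                template[cont] = y
                v = [f(template, c) for f in rate_fns]
                return stoich @ np.asarray(v)
        else:
            def rhs(t, y):
                template[cont] = y[:-1]
                v = [f(template, c) for f in rate_fns]
                dy = stoich @ np.asarray(v)
                return np.append(dy, aux(template))
        return rhs


def build_ode_system(net: HybridPetriNet, partition) -> OdeSystem:
    """ODE system over ``partition``'s continuous species and deterministic
    transitions, with a canonical (sorted) species order."""
    species = sorted(partition.continuous_species)
    det = sorted(partition.deterministic_set)
    place_index = {p: i for i, p in enumerate(net.places)}
    return OdeSystem(net, species, det, place_index)


@dataclass
class IntegrationResult:
    segment: object          # dense-output interpolant over [t0, t_stop]
    reason: str              # "horizon" | "event"
    event_index: int | None
    t_stop: float
    y_stop: np.ndarray


class Integrator:
    """Span-wise adaptive integration front-end with a reinit counter.

    ``integrate`` advances the stored state; ``reinitialise`` replaces it,
    discarding any solver history, and increments ``reinit_count``.  A
    caller that continues integrating without calling ``reinitialise``
    models the accelerated algorithms' continuation after an independent
    stochastic firing.
    """

    def __init__(self, system: OdeSystem, config: IntegratorConfig,
                 y0: np.ndarray | None = None, t0: float = 0.0):
        self.system = system
        self.config = config
        self.t = float(t0)
        self.y = None if y0 is None else np.asarray(y0, float).copy()
        self.reinit_count = 0

    def reinitialise(self, y_new: np.ndarray, t: float) -> None:
        y_new = np.asarray(y_new, float)
        bad = y_new < 0.0
        if bad.any():
            tol = -mdl.NEGATIVE_CLAMP_FACTOR * self.config.atol
            if (y_new < tol).any():
                raise SolverFailure(
                    "state went negative beyond the round-off clamp "
                    f"({y_new.min()})", t, y_new)
            y_new = np.where(bad, 0.0, y_new)
        self.y = y_new.copy()
        self.t = float(t)
        self.reinit_count += 1

    def integrate(self, rhs: Callable, t1: float,
                  events: Sequence[Callable] = ()) -> IntegrationResult:
        """Integrate from the stored (t, y) to ``t1`` or a terminal event.

        Events are scalar functions of (t, y) with sign-change semantics;
        an optional ``direction`` attribute is honoured.  The event time is
        localised by the solver's root finder; ``y_stop`` is the
        dense-output state there.
        """
        t0, y0 = self.t, self.y
        if t1 <= t0:
            raise ValueError(f"t1={t1} must exceed t0={t0}")
        evs = []
        for e in events:
            e.terminal = True
            if not hasattr(e, "direction"):
                e.direction = 0
            evs.append(e)
        sol = solve_ivp(rhs, (t0, t1), y0, method=_METHODS[self.config.method],
                        rtol=self.config.rtol, atol=self.config.atol,
                        max_step=self.config.max_step, dense_output=True,
                        events=evs or None)
        if not sol.success:
            raise SolverFailure(sol.message, float(sol.t[-1]), sol.y[:, -1])
        if sol.status == 1:  # a terminal event fired
            k = next(i for i, te in enumerate(sol.t_events) if len(te))
            t_stop = float(sol.t_events[k][0])
            y_stop = np.asarray(sol.y_events[k][0], float)
            reason, event_index = "event", k
        else:
            t_stop, y_stop = float(sol.t[-1]), sol.y[:, -1].copy()
            reason, event_index = "horizon", None
        self.t, self.y = t_stop, _clamp(y_stop, self.config.atol, t_stop)
        return IntegrationResult(sol.sol, reason, event_index, t_stop, self.y.copy())


def _clamp(y: np.ndarray, atol: float, t: float) -> np.ndarray:
    """Clamp round-off negatives to zero; larger negatives are an error."""
    bad = y < 0.0
    if not bad.any():
        return y
    if (y < -mdl.NEGATIVE_CLAMP_FACTOR * atol).any():
        raise SolverFailure(
            f"negative state beyond round-off clamp ({y.min()})", t, y)
    return np.where(bad, 0.0, y)
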