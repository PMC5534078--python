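"""Programmatic model generators.

Every test model is built here, deterministically, with no external data:
the single-channel calcium model (a two-state stochastic channel gating a
continuous calcium pool), its coloured spatial extension (a channel cluster
feeding a 2-D diffusion grid), and a family of small linear nets with
closed-form references (immigration-death, exponential decay, two-species
equilibrium) used as analytic oracles.  Rate constants are free parameters
with repository defaults chosen to give order-unity event rates; see
docs/methods.md for the derivations of the quoted closed forms.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

from . import expressions as ex
from .coloured import ALL, ColouredNet, IntRange, ProductSet
from .model import HybridPetriNet, Place, Transition

__all__ = [
    "FixtureSpec", "FIXTURES",
    "make_single_channel_calcium", "make_coloured_calcium",
    "make_immigration_death", "make_decay", "make_ab_equilibrium",
    "make_independent_hybrid", "make_coupled_hit", "make_ramping_immigration",
]


def _mass_action(net: HybridPetriNet, k: str) -> ex.Expression:
    return ex.Call("MassAction", (ex.Ref(k, "param"),))


def make_single_channel_calcium(k_open: float = 0.5, k_close: float = 0.5,
                                k_in: float = 2.0,
                                k_pump: float = 1.0) -> HybridPetriNet:
    """Two-state calcium channel gating a continuous calcium pool.

    The channel flips between *close* and *open* (stochastic transitions
    with rates ``k_open*close`` and ``k_close*open``); while open, calcium
    flows in at rate ``k_in*open`` (continuous) and is pumped out at rate
    ``k_pump*Ca``.  With ``p_open = k_open/(k_open+k_close)``, the
    stationary ensemble mean of Ca is ``k_in*p_open/k_pump`` (linear
    first-moment equation).
    """
    net = HybridPetriNet("single_channel_calcium",
                         {"k_open": k_open, "k_close": k_close,
                          "k_in": k_in, "k_pump": k_pump})
    net.add_place(Place("close", "discrete", 1))
    net.add_place(Place("open", "discrete", 0))
    net.add_place(Place("Ca", "continuous", 0.0))
    net.add_transition(Transition("ch_open", "stochastic",
                                  _mass_action(net, "k_open")))
    net.add_transition(Transition("ch_close", "stochastic",
                                  _mass_action(net, "k_close")))
    sym = net.symbols()
    net.add_transition(Transition("Ca_inflow", "continuous",
                                  ex.parse_expression("k_in * open", sym)))
    net.add_transition(Transition("Ca_pump", "continuous",
                                  _mass_action(net, "k_pump")))
    net.add_arc("close", "ch_open").add_arc("ch_open", "open")
    net.add_arc("open", "ch_close").add_arc("ch_close", "close")
    net.add_arc("open", "Ca_inflow", kind="modifier")
    net.add_arc("Ca_inflow", "Ca")
    net.add_arc("Ca", "Ca_pump")
    return net


def make_coloured_calcium(n_channels: int = 3, width: int = 100,
                          height: int = 100,
                          cluster_xy: tuple = (50, 50),
                          D: float = 1.0, k_pump: float = 1.0,
                          k_in: float = 2.0, k_open: float = 0.5,
                          k_close: float = 0.5,
                          ca_preload: dict | None = None) -> ColouredNet:
    """Spatial calcium model: a channel cluster over a 2-D diffusion grid.

    ``chCS = [1..n_channels]`` colours the channel-state places;
    ``Grid2D = [1..width] x [1..height]`` colours the calcium place.  The
    single inflow transition reads the total number of open channels and
    feeds the cluster cell ``cluster_xy``; *diffuse* moves calcium between
    4-neighbour cells (one coloured transition over variables x, y, u, v
    with guard ``(u-x)^2 + (v-y)^2 = 1``); *Ca_pump* drains every cell.
    ``ca_preload`` optionally seeds cells with calcium: {(x, y): amount}.
    """
    cnet = ColouredNet("coloured_calcium",
                       {"k_open": k_open, "k_close": k_close, "k_in": k_in,
                        "k_pump": k_pump, "D": D})
    ch = IntRange("chCS", 1, n_channels) if n_channels > 0 else None
    gx = IntRange("X", 1, width)
    gy = IntRange("Y", 1, height)
    grid = ProductSet("Grid2D", (gx, gy))
    for cs in ([ch] if ch else []) + [gx, gy, grid]:
        cnet.add_colour_set(cs)

    cnet.add_place(Place("Ca", "continuous", 0.0), grid,
                   marking_overrides=dict(ca_preload or {}))
    cnet.add_place(Place("closed", "discrete", 1) if ch else
                   Place("closed", "discrete", 0),
                   ch or IntRange("chCS0", 1, 1))
    cnet.add_place(Place("open", "discrete", 0), ch or IntRange("chCS1", 1, 1))

    var = {"m": ch} if ch else {}
    m = ex.Ref("m", "var") if ch else ex.Num(1.0)
    if ch:
        cnet.add_transition(Transition("ch_open", "stochastic",
                                       ex.Call("MassAction",
                                               (ex.Ref("k_open", "param"),))),
                            variables=var)
        cnet.add_transition(Transition("ch_close", "stochastic",
                                       ex.Call("MassAction",
                                               (ex.Ref("k_close", "param"),))),
                            variables=var)
        cnet.add_arc("closed", "ch_open", "in", colour=(m,))
        cnet.add_arc("open", "ch_open", "out", colour=(m,))
        cnet.add_arc("open", "ch_close", "in", colour=(m,))
        cnet.add_arc("closed", "ch_close", "out", colour=(m,))

    # one inflow instance: constant arc colours only
    cnet.add_transition(Transition(
        "Ca_inflow", "continuous",
        ex.BinOp("*", ex.Ref("k_in", "param"), ex.Ref("open", "place"))))
    cnet.add_arc("open", "Ca_inflow", "in", kind="modifier", colour=ALL)
    cnet.add_arc("Ca", "Ca_inflow", "out",
                 colour=(ex.Num(float(cluster_xy[0])),
                         ex.Num(float(cluster_xy[1]))))

    x, y = ex.Ref("x", "var"), ex.Ref("y", "var")
    u, v = ex.Ref("u", "var"), ex.Ref("v", "var")
    cnet.add_transition(Transition("Ca_pump", "continuous",
                                   ex.Call("MassAction",
                                           (ex.Ref("k_pump", "param"),))),
                        variables={"x": gx, "y": gy})
    cnet.add_arc("Ca", "Ca_pump", "in", colour=(x, y))

    sq = lambda e: ex.BinOp("^", e, ex.Num(2.0))  # noqa: E731
    guard = ex.Compare("=", ex.BinOp("+", sq(ex.BinOp("-", u, x)),
                                     sq(ex.BinOp("-", v, y))), ex.Num(1.0))
    cnet.add_transition(Transition("diffuse", "continuous",
                                   ex.Call("MassAction",
                                           (ex.Ref("D", "param"),))),
                        variables={"x": gx, "y": gy, "u": gx, "v": gy},
                        guard=guard)
    cnet.add_arc("Ca", "diffuse", "in", colour=(x, y))
    cnet.add_arc("Ca", "diffuse", "out", colour=(u, v))
    return cnet


def make_immigration_death(k_in: float = 10.0,
                           k_out: float = 1.0) -> HybridPetriNet:
    """Immigration-death on one species: birth at constant rate ``k_in``,
    per-capita death at ``k_out``.  The stationary law is
    Poisson(``k_in/k_out``): mean and variance both ``k_in/k_out``; the
    transient mean from X(0)=0 is ``(k_in/k_out)(1 - exp(-k_out t))``."""
    net = HybridPetriNet("immigration_death", {"k_in": k_in, "k_out": k_out})
    net.add_place(Place("X", "discrete", 0))
    net.add_transition(Transition("birth", "stochastic",
                                  ex.Ref("k_in", "param")))
    net.add_transition(Transition("death", "stochastic",
                                  _mass_action(net, "k_out")))
    net.add_arc("birth", "X")
    net.add_arc("X", "death")
    return net


def make_decay(k: float = 1.0, x0: float = 100) -> HybridPetriNet:
    """First-order decay X -> 0; closed form ``X(t) = X0 exp(-k t)`` under
    the deterministic interpretation."""
    net = HybridPetriNet("decay", {"k": k})
    net.add_place(Place("X", "discrete", x0))
    net.add_transition(Transition("decay", "stochastic", _mass_action(net, "k")))
    net.add_arc("X", "decay")
    return net


def make_ab_equilibrium(kf: float = 1.0, kr: float = 1.0, a0: float = 100,
                        b0: float = 0) -> HybridPetriNet:
    """A <-> B with mass-action rates; A + B is a stoichiometric invariant
    under every algorithm."""
    net = HybridPetriNet("ab_equilibrium", {"kf": kf, "kr": kr})
    net.add_place(Place("A", "continuous", a0))
    net.add_place(Place("B", "continuous", b0))
    net.add_transition(Transition("fwd", "continuous", _mass_action(net, "kf")))
    net.add_transition(Transition("rev", "continuous", _mass_action(net, "kr")))
    net.add_arc("A", "fwd").add_arc("fwd", "B")
    net.add_arc("B", "rev").add_arc("rev", "A")
    return net


def make_independent_hybrid(k_in: float = 10.0, k_out: float = 1.0,
                            k_dec: float = 0.3,
                            y0: float = 5.0) -> HybridPetriNet:
    """Stochastic immigration-death on X next to continuous decay of Y.

    The slow propensities (``k_in``, ``k_out*X``) never read Y and the
    firings never touch Y, so every stochastic reaction is *independent*:
    the accelerated and rejection-based algorithms never have to
    reinitialise the ODE solver, while the exact jump-equation method
    restarts it on every event.
    """
    net = HybridPetriNet("independent_hybrid",
                         {"k_in": k_in, "k_out": k_out, "k_dec": k_dec})
    net.add_place(Place("X", "discrete", 0))
    net.add_place(Place("Y", "continuous", y0))
    net.add_transition(Transition("birth", "stochastic",
                                  ex.Ref("k_in", "param")))
    net.add_transition(Transition("death", "stochastic",
                                  _mass_action(net, "k_out")))
    net.add_transition(Transition("decay", "continuous",
                                  _mass_action(net, "k_dec")))
    net.add_arc("birth", "X")
    net.add_arc("X", "death")
    net.add_arc("Y", "decay")
    return net


def make_coupled_hit(k: float = 1.0, k_c: float = 2.0,
                     y0: float = 1.0) -> HybridPetriNet:
    """A slow counting reaction whose propensity reads a decaying continuous
    species: ``a(t) = k_c * Y(t)`` with ``Y(t) = y0 exp(-k t)``.

    The first jump time solves ``(k_c*y0/k)(1 - exp(-k tau)) = -log r``,
    giving a closed-form oracle for the jump-equation root finder.
    """
    net = HybridPetriNet("coupled_hit", {"k": k, "k_c": k_c})
    net.add_place(Place("Y", "continuous", y0))
    net.add_place(Place("C", "discrete", 0))
    net.add_transition(Transition("decay", "continuous", _mass_action(net, "k")))
    net.add_transition(Transition("hit", "stochastic",
                                  ex.parse_expression(
                                      "k_c * Y",
                                      ex.SymbolTable.make(["Y", "C"],
                                                          ["k", "k_c"]))))
    net.add_arc("Y", "decay")
    net.add_arc("Y", "hit", kind="modifier")
    net.add_arc("hit", "C")
    return net


def make_ramping_immigration(k_ramp: float = 20.0,
                             k_out: float = 1.0) -> HybridPetriNet:
    """Immigration-death whose immigration rate ramps up via a driver
    species R (``dR/dt = k_ramp`` deterministically; immigration propensity
    equals R).  Because all rates are linear, the mean of X obeys the same
    moment equation under every interpretation, while the propensities
    sweep from slow to fast — the workload dynamic repartitioning targets.
    """
    net = HybridPetriNet("ramping_immigration",
                         {"k_ramp": k_ramp, "k_out": k_out})
    net.add_place(Place("R", "continuous", 0))
    net.add_place(Place("X", "discrete", 0))
    net.add_transition(Transition("ramp", "continuous",
                                  ex.Ref("k_ramp", "param"),
                                  partition_hint="deterministic"))
    net.add_transition(Transition("immigrate", "stochastic",
                                  ex.parse_expression(
                                      "R", ex.SymbolTable.make(["R", "X"]))))
    net.add_transition(Transition("death", "stochastic",
                                  _mass_action(net, "k_out")))
    net.add_arc("ramp", "R")
    net.add_arc("R", "immigrate", kind="modifier")
    net.add_arc("immigrate", "X")
    net.add_arc("X", "death")
    return net


@dataclass(frozen=True)
class FixtureSpec:
    """Registry entry: a named deterministic generator plus the closed-form
    reference documented for it."""

    name: str
    factory: Callable
    description: str
    reference: str


FIXTURES = {
    s.name: s for s in [
        FixtureSpec("single-channel-calcium", make_single_channel_calcium,
                    "two-state channel gating a continuous calcium pool",
                    "stationary mean Ca = k_in*p_open/k_pump, "
                    "p_open = k_open/(k_open+k_close)"),
        FixtureSpec("coloured-calcium", make_coloured_calcium,
                    "channel cluster on a width x height diffusion grid",
                    "unfolds to 2*n_channels + width*height places"),
        FixtureSpec("immigration-death", make_immigration_death,
                    "constant birth, per-capita death",
                    "stationary Poisson(k_in/k_out)"),
        FixtureSpec("decay", make_decay, "first-order decay",
                    "X(t) = X0*exp(-k*t)"),
        FixtureSpec("ab-equilibrium", make_ab_equilibrium,
                    "reversible isomerisation", "A+B conserved"),
        FixtureSpec("independent-hybrid", make_independent_hybrid,
                    "immigration-death beside an uncoupled continuous decay",
                    "all stochastic reactions independent"),
        FixtureSpec("coupled-hit", make_coupled_hit,
                    "slow reaction driven by a decaying continuous species",
                    "first jump solves (k_c*y0/k)(1-exp(-k*tau)) = -log r"),
        FixtureSpec("ramping-immigration", make_ramping_immigration,
                    "immigration rate ramped by a deterministic driver",
                    "E[X](t) identical across interpretations (linear rates)"),
    ]
}
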