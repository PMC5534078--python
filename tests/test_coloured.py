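"""Coloured nets: binding enumeration, unfolding, size reports."""

import numpy as np
import pytest

from hpnsim import expressions as ex
from hpnsim import fixtures as fx
from hpnsim import model as mdl
from hpnsim.coloured import (ALL, ColouredNet, IntRange, ProductSet,
                             UnfoldError, enumerate_bindings, flat_name,
                             size_report, unfold)
from hpnsim.model import HybridPetriNet, Place, Transition


def _channel_only(n: int) -> ColouredNet:
    """The discrete channel subnet alone: closed/open over n channel
    colours with opening/closing transitions."""
    cnet = ColouredNet("channels", {"k_open": 1.0, "k_close": 1.0})
    ch = IntRange("chCS", 1, n)
    cnet.add_colour_set(ch)
    cnet.add_place(Place("closed", "discrete", 1), ch)
    cnet.add_place(Place("open", "discrete", 0), ch)
    m = ex.Ref("m", "var")
    for tid, src, dst, k in (("ch_open", "closed", "open", "k_open"),
                             ("ch_close", "open", "closed", "k_close")):
        cnet.add_transition(
            Transition(tid, "stochastic",
                       ex.Call("MassAction", (ex.Ref(k, "param"),))),
            variables={"m": ch})
        cnet.add_arc(src, tid, "in", colour=(m,))
        cnet.add_arc(dst, tid, "out", colour=(m,))
    return cnet


class TestBindings:
    def test_unguarded_transition_has_one_instance_per_colour(self):
        cnet = _channel_only(3)
        assert len(enumerate_bindings(cnet.transitions["ch_open"])) == 3

    def test_false_guard_yields_no_bindings(self):
        cnet = _channel_only(3)
        ct = cnet.transitions["ch_open"]
        ct.guard = ex.Compare("=", ex.Num(0.0), ex.Num(1.0))
        assert enumerate_bindings(ct) == []

    def test_guard_restricts_bindings(self):
        cnet = _channel_only(5)
        ct = cnet.transitions["ch_open"]
        ct.guard = ex.Compare("<", ex.Ref("m", "var"), ex.Num(3.0))
        assert [b["m"] for b in enumerate_bindings(ct)] == [1, 2]

    @pytest.mark.parametrize("w,h", [(2, 2), (4, 3), (6, 6)])
    def test_four_neighbour_bindings_match_directed_edge_count(self, w, h):
        """The diffusion guard admits exactly the ordered 4-adjacent cell
        pairs: 2*(2*w*h) - 2*(w+h) directed edges of a w x h grid."""
        cnet = fx.make_coloured_calcium(1, w, h, (1, 1))
        got = enumerate_bindings(cnet.transitions["diffuse"],
                                 cnet.parameters)
        expected = h * 2 * (w - 1) + w * 2 * (h - 1)
        assert len(got) == expected
        for b in got:
            assert abs(b["u"] - b["x"]) + abs(b["v"] - b["y"]) == 1

    def test_canonical_order(self):
        cnet = fx.make_coloured_calcium(1, 3, 3, (1, 1))
        got = enumerate_bindings(cnet.transitions["diffuse"],
                                 cnet.parameters)
        keys = [tuple(b[v] for v in ("x", "y", "u", "v")) for b in got]
        assert keys == sorted(keys)


class TestUnfold:
    def test_channel_subnet_three_identical_copies(self):
        net = unfold(_channel_only(3))
        assert len(net.places) == 6
        assert len(net.transitions) == 6
        assert mdl.validate(net) == []
        assert mdl.stoichiometry(net, "ch_open__2") == {
            "closed__2": -1.0, "open__2": 1.0}

    def test_constant_arc_transition_has_single_instance(self):
        cnet = fx.make_coloured_calcium(2, 4, 4, (2, 2))
        net = unfold(cnet)
        inflow = [t for t in net.transitions if t.startswith("Ca_inflow")]
        assert inflow == ["Ca_inflow"]
        # its rate reads the total number of open channels
        deps = ex.dependencies(net.expanded_rate("Ca_inflow"))
        assert deps == {"open__1", "open__2"}

    def test_small_grid_counts(self):
        net = unfold(fx.make_coloured_calcium(1, 2, 2, (1, 1)))
        # 2 channel-state places + 4 grid cells; 8 = directed edges of 2x2
        assert len(net.places) == 6
        diffusions = [t for t in net.transitions if t.startswith("diffuse")]
        assert len(diffusions) == 8

    def test_singleton_colouring_is_identity_up_to_renaming(self,
                                                            calcium_net):
        one = IntRange("one", 1, 1)
        cnet = ColouredNet("wrapped", calcium_net.parameters)
        cnet.add_colour_set(one)
        for p in calcium_net.places.values():
            cnet.add_place(Place(p.id, p.kind, p.initial_marking), one)
        for t in calcium_net.transitions.values():
            cnet.add_transition(Transition(t.id, t.kind, t.rate))
            for a in calcium_net.input_arcs(t.id):
                cnet.add_arc(a.source, t.id, "in", a.kind, a.weight,
                             (ex.Num(1.0),))
            for a in calcium_net.output_arcs(t.id):
                cnet.add_arc(a.target, t.id, "out", a.kind, a.weight,
                             (ex.Num(1.0),))
        net = unfold(cnet)
        rename = {pid: flat_name(pid, 1) for pid in calcium_net.places}
        assert set(net.places) == set(rename.values())
        assert set(net.transitions) == set(calcium_net.transitions)
        for tid in calcium_net.transitions:
            orig = {rename[p]: v for p, v in
                    mdl.stoichiometry(calcium_net, tid).items()}
            assert mdl.stoichiometry(net, tid) == orig

    def test_unfolding_is_declaration_order_independent(self):
        def build(reverse: bool) -> ColouredNet:
            cnet = ColouredNet("g", {"k": 1.0})
            cs = IntRange("cs", 1, 3)
            cnet.add_colour_set(cs)
            places = [("a", 1), ("b", 0)]
            transitions = ["t1", "t2"]
            if reverse:
                places.reverse()
                transitions.reverse()
            for pid, m0 in places:
                cnet.add_place(Place(pid, "discrete", m0), cs)
            v = ex.Ref("m", "var")
            for tid in transitions:
                cnet.add_transition(
                    Transition(tid, "stochastic",
                               ex.Call("MassAction", (ex.Ref("k", "param"),))),
                    variables={"m": cs})
                cnet.add_arc("a", tid, "in", colour=(v,))
                cnet.add_arc("b", tid, "out", colour=(v,))
            return cnet

        assert unfold(build(False)) == unfold(build(True))

    def test_out_of_range_colour_without_guard_is_an_error(self):
        cnet = ColouredNet("bad")
        cs = IntRange("cs", 1, 3)
        cnet.add_colour_set(cs)
        cnet.add_place(Place("a", "discrete", 1), cs)
        m = ex.Ref("m", "var")
        cnet.add_transition(Transition("shift", "stochastic", ex.Num(1.0)),
                            variables={"m": cs})
        cnet.add_arc("a", "shift", "in", colour=(m,))
        cnet.add_arc("a", "shift", "out",
                     colour=(ex.BinOp("+", m, ex.Num(1.0)),))  # m+1 > 3
        with pytest.raises(UnfoldError, match="guard must exclude"):
            unfold(cnet)

    def test_guard_excluding_out_of_range_is_fine(self):
        cnet = ColouredNet("ok")
        cs = IntRange("cs", 1, 3)
        cnet.add_colour_set(cs)
        cnet.add_place(Place("a", "discrete", 1), cs)
        m = ex.Ref("m", "var")
        cnet.add_transition(Transition("shift", "stochastic", ex.Num(1.0)),
                            variables={"m": cs},
                            guard=ex.Compare("<", m, ex.Num(3.0)))
        cnet.add_arc("a", "shift", "in", colour=(m,))
        cnet.add_arc("a", "shift", "out",
                     colour=(ex.BinOp("+", m, ex.Num(1.0)),))
        net = unfold(cnet)
        assert sorted(net.transitions) == ["shift__1", "shift__2"]

    def test_no_channels_degenerate_model_unfolds_clean(self):
        cnet = fx.make_coloured_calcium(0, 3, 3, (2, 2))
        net = unfold(cnet)
        assert mdl.validate(net) == []
        assert not any(t.kind == "stochastic"
                       for t in net.transitions.values())

    def test_marking_overrides_seed_specific_cells(self):
        cnet = fx.make_coloured_calcium(1, 3, 3, (2, 2),
                                        ca_preload={(2, 2): 7.5})
        net = unfold(cnet)
        assert net.places["Ca__2_2"].initial_marking == 7.5
        assert net.places["Ca__1_1"].initial_marking == 0.0


class TestSizeReport:
    @pytest.mark.parametrize("n,w,h", [(1, 2, 2), (3, 4, 3), (2, 5, 5)])
    def test_totals_match_materialised_unfolding(self, n, w, h):
        cnet = fx.make_coloured_calcium(n, w, h, (1, 1))
        rep = size_report(cnet)
        net = unfold(cnet)
        assert sum(rep["places"].values()) == len(net.places)
        assert sum(rep["transitions"].values()) == len(net.transitions)
        for base, count in rep["transitions"].items():
            assert count == sum(1 for t in net.transitions
                                if t == base or t.startswith(base + "__"))
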