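"""Discrete-event engine: propensities, direct method, dependency graph,
fluctuation intervals and rejection-based selection."""

import math

import numpy as np
import pytest
from scipy import stats

from hpnsim import expressions as ex
from hpnsim import model as mdl
from hpnsim import stochastic as st
from hpnsim.hybrid import make_partition
from hpnsim.model import HybridPetriNet, Place, Transition

from conftest import StubStream, random_net


class TestPropensities:
    def test_calcium_initial_state(self, calcium_net):
        ps = st.compute_propensities(calcium_net,
                                     {"close": 1, "open": 0, "Ca": 0.0},
                                     ["ch_open", "ch_close"])
        a = dict(zip(ps.transition_ids, ps.a))
        assert a["ch_open"] == calcium_net.parameters["k_open"]
        assert a["ch_close"] == 0.0

    def test_all_disabled_total_is_zero(self, immigration_death):
        ps = st.compute_propensities(
            immigration_death, {"X": 0}, ["death"])
        assert ps.a0 == 0.0

    @pytest.mark.parametrize("seed", range(6))
    def test_evaluator_matches_per_transition_recomputation(self, seed):
        """The compiled evaluator agrees with transition-by-transition
        tree-walk recomputation at random markings."""
        net = random_net(seed)
        tids = sorted(net.transitions)
        place_index = {p: i for i, p in enumerate(net.places)}
        evaluator = st.PropensityEvaluator(net, tids, place_index)
        rng = np.random.default_rng(seed + 100)
        for _ in range(25):
            m = {p: float(rng.integers(0, 4)) for p in net.places}
            x = np.array([m[p] for p in place_index])
            ref = st.compute_propensities(net, m, tids)
            np.testing.assert_allclose(evaluator.all_propensities(x), ref.a,
                                       rtol=1e-12)

    def test_combinatorial_mass_action_uses_falling_factorial(self):
        net = HybridPetriNet(parameters={"k": 2.0})
        net.add_place(Place("A", "discrete", 5))
        net.add_transition(Transition(
            "dimerise", "stochastic",
            ex.Call("MassAction", (ex.Ref("k", "param"),)),
            combinatorial=True))
        net.add_arc("A", "dimerise", weight=2.0)
        evaluator = st.PropensityEvaluator(net, ["dimerise"], {"A": 0})
        # k * A(A-1)/2! = 2 * 5*4/2 = 20
        assert evaluator.propensity(0, np.array([5.0])) == 20.0


class TestDirectMethod:
    def test_closed_form_waiting_time(self):
        ps = st.PropensityState(("t0",), np.array([10.0]))
        rng = StubStream([math.exp(-1.0), 0.5])
        j, tau = st.direct_method_step(ps, rng)
        assert j == 0
        assert tau == pytest.approx(0.1)

    def test_cumulative_selection(self):
        ps = st.PropensityState(("a", "b", "c"), np.array([2.0, 3.0, 5.0]))
        rng = StubStream([0.5, 0.45])  # r2*a0 = 4.5 <= cumsum 5 at index 1
        j, _ = st.direct_method_step(ps, rng)
        assert j == 1

    def test_zero_total_signals_no_event(self):
        ps = st.PropensityState(("t0",), np.array([0.0]))
        with pytest.raises(st.NoStochasticEvent):
            st.direct_method_step(ps, st.RandomStream(0))

    def test_waiting_times_and_selection_frequencies(self):
        """10^5 draws: mean waiting time = 1/a0 within 3 SE and selection
        frequencies proportional to propensities (chi-squared p > 0.001)."""
        a = np.array([2.0, 3.0, 5.0])
        ps = st.PropensityState(("a", "b", "c"), a)
        rng = st.RandomStream(42)
        n = 100_000
        taus = np.empty(n)
        counts = np.zeros(3)
        for i in range(n):
            j, tau = st.direct_method_step(ps, rng)
            taus[i] = tau
            counts[j] += 1
        mean, se = taus.mean(), taus.std(ddof=1) / math.sqrt(n)
        assert abs(mean - 1.0 / ps.a0) < 3 * se
        p = stats.chisquare(counts, n * a / a.sum()).pvalue
        assert p > 0.001

    def test_identical_seed_identical_sequence(self):
        draws1 = [st.RandomStream(7, 3).uniform() for _ in range(5)]
        draws2 = [st.RandomStream(7, 3).uniform() for _ in range(5)]
        assert draws1 == draws2
        assert [st.RandomStream(7, 4).uniform()
                for _ in range(5)] != draws1


class TestDependencyGraph:
    def test_channel_reactions_are_dependent(self, calcium_net):
        part = make_partition(calcium_net)
        dependent = st.classify_dependent(calcium_net, part)
        # ch_open/ch_close flip `open`, which Ca_inflow's rate reads
        assert dependent == {"ch_open", "ch_close"}

    def test_isolated_reaction_is_independent(self):
        from hpnsim.fixtures import make_independent_hybrid
        net = make_independent_hybrid()
        part = make_partition(net)
        assert st.classify_dependent(net, part) == set()

    @pytest.mark.parametrize("seed", range(6))
    def test_graph_soundness_against_full_recomputation(self, seed):
        """After firing j, refreshing only graph[j] reproduces the full
        recomputation at the new state (exhaustive over transitions)."""
        net = random_net(seed)
        part = make_partition(net)
        graph = st.build_dependency_graph(net, part)
        tids = sorted(part.stochastic_set)
        rng = np.random.default_rng(seed)
        for j_id in tids:
            m = {p: float(rng.integers(1, 5)) for p in net.places}
            if not mdl.enabled(net, j_id, m):
                continue
            before = st.compute_propensities(net, m, tids)
            m_after = dict(m)
            for pid, dv in mdl.stoichiometry(net, j_id, m).items():
                m_after[pid] += dv
            if min(m_after.values()) < 0:
                continue
            after_full = st.compute_propensities(net, m_after, tids)
            patched = before.a.copy()
            for k_id in graph[j_id]:
                k = tids.index(k_id)
                patched[k] = after_full.a[k]
            np.testing.assert_allclose(patched, after_full.a, rtol=1e-12)

    @pytest.mark.parametrize("seed", range(6))
    def test_graph_matches_pairwise_oracle(self, seed):
        net = random_net(seed)
        part = make_partition(net)
        graph = st.build_dependency_graph(net, part)
        tids = sorted(part.stochastic_set)
        for j in tids:
            changed = set(mdl.stoichiometry(net, j))
            expect = set()
            for k in tids:
                reads = ex.dependencies(net.expanded_rate(k))
                reads |= {a.source for a in net.input_arcs(k)
                          if a.kind != "modifier"}
                if reads & changed:
                    expect.add(k)
            assert graph[j] == expect


class TestFluctuationInterval:
    def test_relative_widening(self, immigration_death):
        net = immigration_death
        net.places["X"].kind = "continuous"  # no discrete floor
        fi = st.make_fluctuation_interval(net, {"X": 100.0}, ["X"], 0.1, 2.0)
        assert (fi.lo["X"], fi.hi["X"]) == pytest.approx((90.0, 110.0))

    def test_zero_state_clamps_to_floor(self, immigration_death):
        fi = st.make_fluctuation_interval(immigration_death, {"X": 0},
                                          ["X"], 0.1, 2.0)
        assert (fi.lo["X"], fi.hi["X"]) == (0.0, 2.0)

    def test_bad_delta_rejected(self, immigration_death):
        with pytest.raises(ValueError):
            st.make_fluctuation_interval(immigration_death, {"X": 1},
                                         ["X"], 1.5, 2.0)

    def test_propensity_bounds_contain_sampled_propensities(self,
                                                            immigration_death):
        net = immigration_death
        fi = st.make_fluctuation_interval(net, {"X": 10}, ["X"], 0.2, 2.0)
        st.propensity_bounds(net, fi, ("birth", "death"), {"X": 10})
        rng = np.random.default_rng(0)
        for _ in range(300):
            x = rng.uniform(fi.lo["X"], fi.hi["X"])
            ps = st.compute_propensities(net, {"X": round(x)},
                                         ("birth", "death"))
            inside = (fi.lo["X"] <= round(x) <= fi.hi["X"])
            if inside:
                assert np.all(ps.a <= fi.a_high + 1e-9)
                assert np.all(ps.a >= fi.a_low - 1e-9)

    def test_possibly_disabled_reaction_gets_zero_lower_bound(self):
        net = HybridPetriNet(parameters={"k": 1.0})
        net.add_place(Place("A", "discrete", 1))
        net.add_transition(Transition(
            "t", "stochastic", ex.Call("MassAction", (ex.Ref("k", "param"),))))
        net.add_arc("A", "t")
        fi = st.make_fluctuation_interval(net, {"A": 1}, ["A"], 0.1, 2.0)
        st.propensity_bounds(net, fi, ("t",), {"A": 1})
        assert fi.a_low[0] == 0.0       # interval [0,3] includes disabled A=0
        assert fi.a_high[0] == 3.0


class TestRssaSelect:
    def _tight_fi(self, net, marking, tids):
        """Degenerate fluctuation interval: bounds equal the exact
        propensities, so the squeeze test always accepts first try."""
        fi = st.FluctuationInterval(tuple(marking), dict(marking),
                                    dict(marking))
        ps = st.compute_propensities(net, marking, tids)
        fi.a_low = ps.a.copy()
        fi.a_high = ps.a.copy()
        return fi

    def test_tight_bounds_match_direct_method_distribution(self,
                                                           immigration_death):
        """With exact bounds the rejection sampler reduces to the direct
        method: waiting times are Exp(a0) (KS p > 0.001) and selection
        frequencies are proportional to propensities."""
        net = immigration_death
        marking = {"X": 5}
        tids = ("birth", "death")
        fi = self._tight_fi(net, marking, tids)
        rng = st.RandomStream(3)
        n = 10_000
        taus, counts = np.empty(n), np.zeros(2)
        for i in range(n):
            j, t = st.rssa_select(net, fi, tids, lambda tt: marking, rng, 0.0)
            taus[i] = t
            counts[j] += 1
        a0 = fi.a_high_total
        assert stats.kstest(taus, "expon", args=(0, 1 / a0)).pvalue > 0.001
        expected = n * fi.a_high / a0
        assert stats.chisquare(counts, expected).pvalue > 0.001

    def test_loose_bounds_acceptance_rate(self, immigration_death):
        """With upper bounds inflated 2x (and no squeeze shortcut), the
        empirical acceptance rate approaches mean(a_j / a_high_j) = 1/2."""
        net = immigration_death
        marking = {"X": 5}
        tids = ("birth", "death")
        fi = self._tight_fi(net, marking, tids)
        fi.a_high = 2.0 * fi.a_high
        fi.a_low = np.zeros_like(fi.a_low)  # disable the squeeze shortcut
        calls = [0]

        def provider(t):
            calls[0] += 1
            return marking

        rng = st.RandomStream(4)
        n = 4000
        for _ in range(n):
            st.rssa_select(net, fi, tids, provider, rng, 0.0)
        rate = n / calls[0]
        se = math.sqrt(0.25 / calls[0])
        assert abs(rate - 0.5) < 3 * se + 0.01

    def test_bounds_exit_reported(self, immigration_death):
        fi = self._tight_fi(immigration_death, {"X": 5}, ("birth", "death"))
        out = st.rssa_select(immigration_death, fi, ("birth", "death"),
                             lambda t: st.BoundsExit(t), st.RandomStream(0))
        assert isinstance(out, st.BoundsExit)

    def test_zero_upper_bounds_signal_no_event(self, immigration_death):
        fi = self._tight_fi(immigration_death, {"X": 0}, ("death",))
        with pytest.raises(st.NoStochasticEvent):
            st.rssa_select(immigration_death, fi, ("death",),
                           lambda t: {"X": 0}, st.RandomStream(0))
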