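"""Hybrid synchronisation algorithms, partitions, timed transitions and
ensembles."""

import math

import numpy as np
import pytest

from hpnsim import expressions as ex
from hpnsim import fixtures as fx
from hpnsim import hybrid as hy
from hpnsim import model as mdl
from hpnsim.model import HybridPetriNet, Place, Transition
from hpnsim.ode import IntegratorConfig
from hpnsim.stochastic import RandomStream

FAST = IntegratorConfig(method="nonstiff")


def _cfg(**kw):
    kw.setdefault("integrator", FAST)
    return hy.SimulationConfig(**kw)


class TestPartition:
    def test_default_partition_follows_transition_kinds(self, calcium_net):
        part = hy.make_partition(calcium_net)
        assert part.stochastic_set == {"ch_open", "ch_close"}
        assert part.deterministic_set == {"Ca_inflow", "Ca_pump"}
        assert part.continuous_species == {"Ca"}
        assert part.discrete_species == {"open", "close"}

    def test_species_written_by_deterministic_regime_promoted(self):
        """A declared-discrete species written by a deterministic-regime
        transition is classed continuous (both-regimes rule)."""
        net = fx.make_ramping_immigration()
        part = hy.make_partition(net)  # ramp is pinned deterministic
        assert "R" in part.continuous_species

    def test_partition_hint_overrides_kind(self, calcium_net):
        calcium_net.transitions["Ca_pump"].partition_hint = "stochastic"
        part = hy.make_partition(calcium_net)
        assert "Ca_pump" in part.stochastic_set

    def test_overlapping_regimes_rejected(self, calcium_net):
        with pytest.raises(ValueError, match="overlap"):
            hy.make_partition(calcium_net,
                              stochastic=["ch_open", "ch_close", "Ca_pump"],
                              deterministic=["Ca_inflow", "Ca_pump"])

    def test_incomplete_cover_rejected(self, calcium_net):
        with pytest.raises(ValueError, match="cover"):
            hy.make_partition(calcium_net, stochastic=["ch_open"],
                              deterministic=["Ca_inflow"])


class TestDynamicPartition:
    def test_threshold_rule(self, immigration_death):
        # propensity of birth = 10 >= 5, substrate set empty -> deterministic
        part = hy.dynamic_partition(immigration_death, {"X": 200},
                                    lambda_prop=5.0, n_substrate=100.0)
        assert "birth" in part.deterministic_set
        assert "death" in part.deterministic_set  # a = 200 >= 5, X >= 100

    def test_empty_substrate_forces_stochastic(self, immigration_death):
        part = hy.dynamic_partition(immigration_death, {"X": 0},
                                    lambda_prop=0.0, n_substrate=1.0)
        assert "death" in part.stochastic_set

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_two_predicate_oracle(self, seed, calcium_net):
        rng = np.random.default_rng(seed)
        lam, nsub = float(rng.uniform(0.1, 5)), float(rng.integers(0, 4))
        marking = {p: float(rng.integers(0, 6))
                   for p in calcium_net.places}
        part = hy.dynamic_partition(calcium_net, marking, lam, nsub)
        for tid, t in calcium_net.transitions.items():
            a = 0.0
            if mdl.enabled(calcium_net, tid, marking):
                a = max(0.0, ex.evaluate(calcium_net.expanded_rate(tid),
                                         marking, calcium_net.parameters))
            subs = {arc.source for arc in calcium_net.input_arcs(tid)
                    if arc.kind in ("standard", "read")}
            fast = a >= lam and all(marking[p] >= nsub for p in subs)
            assert (tid in part.deterministic_set) == fast


class TestExactHybrid:
    def test_constant_propensities_replay_direct_method(self,
                                                        immigration_death):
        """With no continuous coupling the jump equation collapses to the
        exponential of the direct method: identical streams give identical
        event sequences."""
        cfg = _cfg(t_end=50.0, seed=9, output_points=51)
        ssa = hy.pure_ssa_run(immigration_death, cfg,
                              rng=RandomStream(9, 0))
        part = hy.make_partition(immigration_death)
        hr = hy.hr_exact_run(immigration_death, part, cfg,
                             rng=RandomStream(9, 0))
        np.testing.assert_array_equal(ssa.meta["event_times"],
                                      hr.meta["event_times"])
        assert ssa.meta["event_ids"] == hr.meta["event_ids"]
        np.testing.assert_array_equal(ssa.values, hr.values)

    def test_first_jump_matches_closed_form_root(self):
        """Slow propensity k_c*Y with Y(t) = y0*exp(-k*t): the first firing
        time solves (k_c*y0/k)(1 - exp(-k*tau)) = -log r."""
        net = fx.make_coupled_hit(k=1.0, k_c=5.0, y0=1.0)
        cfg = _cfg(t_end=10.0, seed=2, output_points=11)
        tr = hy.hr_exact_run(net, None, cfg, rng=RandomStream(2, 0))
        r = RandomStream(2, 0).uniform()  # the run's first draw is the target
        target = -math.log(r)
        assert target < 5.0  # an event exists within the budget
        tau = -math.log(1.0 - target / 5.0)
        assert tr.meta["event_times"][0] == pytest.approx(tau, abs=1e-6)

    def test_zero_stochastic_transitions_equals_pure_ode(self):
        net = fx.make_ab_equilibrium()
        cfg = _cfg(t_end=5.0, seed=0, output_points=21)
        hr = hy.hr_exact_run(net, None, cfg)
        ode = hy.pure_ode_run(net, cfg)
        np.testing.assert_allclose(hr.values, ode.values, rtol=1e-12)
        assert hr.meta["n_events"] == 0


class TestAcceleratedAndHrssa:
    def test_decoupled_event_times_agree_with_exact(self):
        """Slow propensities independent of the continuous state: shared
        random stream gives event-by-event agreement at root tolerance."""
        net = fx.make_independent_hybrid()
        part = hy.make_partition(net)
        cfg = _cfg(t_end=10.0, seed=5, output_points=11)
        hr = hy.hr_exact_run(net, part, cfg, rng=RandomStream(5, 0))
        ac = hy.accelerated_run(net, part, cfg, rng=RandomStream(5, 0))
        assert hr.meta["event_ids"] == ac.meta["event_ids"]
        np.testing.assert_allclose(hr.meta["event_times"],
                                   ac.meta["event_times"], atol=1e-9)

    def test_independent_reactions_skip_reinitialisation(self):
        net = fx.make_independent_hybrid()
        part = hy.make_partition(net)
        cfg = _cfg(t_end=8.0, seed=6, output_points=9)
        hr = hy.hr_exact_run(net, part, cfg, rng=RandomStream(6, 0))
        ac = hy.accelerated_run(net, part, cfg, rng=RandomStream(6, 0))
        rs = hy.hrssa_run(net, part, cfg, rng=RandomStream(6, 1))
        assert hr.meta["n_events"] > 0
        assert hr.meta["reinit_count"] == hr.meta["n_events"]
        assert ac.meta["reinit_count"] == 0
        assert rs.meta["reinit_count"] == 0

    def test_dependent_reactions_do_reinitialise(self, calcium_net):
        cfg = _cfg(t_end=10.0, seed=7, output_points=11)
        ac = hy.accelerated_run(calcium_net, None, cfg)
        assert ac.meta["n_events"] > 0
        assert ac.meta["reinit_count"] == ac.meta["n_events"]

    def test_reinit_never_exceeds_event_count(self, calcium_net):
        """The exact method reinitialises once per event; the accelerated
        and rejection-based methods never more often than that (the
        mechanism behind their speed-ups)."""
        for seed in (1, 2, 3):
            cfg = _cfg(t_end=10.0, seed=seed, output_points=11)
            hr = hy.hr_exact_run(calcium_net, None, cfg,
                                 rng=RandomStream(seed, 0))
            ac = hy.accelerated_run(calcium_net, None, cfg,
                                    rng=RandomStream(seed, 0))
            rs = hy.hrssa_run(calcium_net, None, cfg,
                              rng=RandomStream(seed, 0))
            assert hr.meta["reinit_count"] == hr.meta["n_events"]
            assert ac.meta["reinit_count"] <= ac.meta["n_events"]
            assert rs.meta["reinit_count"] <= rs.meta["n_events"]

    def test_hrssa_zero_stochastic_equals_pure_ode(self):
        net = fx.make_ab_equilibrium()
        cfg = _cfg(t_end=5.0, seed=0, output_points=21)
        rs = hy.hrssa_run(net, None, cfg)
        ode = hy.pure_ode_run(net, cfg)
        np.testing.assert_allclose(rs.values, ode.values, rtol=1e-12)

    def test_accelerated_zero_stochastic_equals_pure_ode(self):
        net = fx.make_ab_equilibrium()
        cfg = _cfg(t_end=5.0, seed=0, output_points=21)
        ac = hy.accelerated_run(net, None, cfg)
        ode = hy.pure_ode_run(net, cfg)
        np.testing.assert_allclose(ac.values, ode.values, rtol=1e-12)


class TestPureModes:
    def test_pure_ode_decay_closed_form(self):
        net = fx.make_decay(k=1.0, x0=100)
        cfg = _cfg(t_end=1.0, seed=0, output_points=11)
        tr = hy.pure_ode_run(net, cfg)
        assert tr.column("X")[-1] == pytest.approx(
            100.0 * math.exp(-1.0), rel=10 * FAST.rtol)

    def test_pure_ssa_stationary_moments(self, immigration_death):
        """Stationary law is Poisson(10): mean and variance 10 within 3 SE
        over spaced samples of one long run."""
        grid = np.arange(10.0, 10.0 + 3.0 * 3000, 3.0)
        cfg = hy.SimulationConfig(algorithm="pure_ssa", t_end=grid[-1],
                                  output_grid=grid, seed=11)
        tr = hy.pure_ssa_run(immigration_death, cfg)
        x = tr.column("X")
        n = len(x)
        se_mean = x.std(ddof=1) / math.sqrt(n)
        assert abs(x.mean() - 10.0) < 3 * se_mean
        m4 = np.mean((x - x.mean()) ** 4)
        se_var = math.sqrt(max(m4 - x.var() ** 2, 0.0) / n)
        assert abs(x.var(ddof=1) - 10.0) < 3 * se_var

    def test_pure_ssa_rejects_non_integer_marking(self):
        net = HybridPetriNet()
        net.add_place(Place("c", "continuous", 0.5))
        net.add_transition(Transition("t", "stochastic", ex.Num(1.0)))
        net.add_arc("c", "t")
        with pytest.raises(mdl.NetError, match="marking not integer"):
            hy.pure_ssa_run(net, _cfg(t_end=1.0))

    def test_trace_discreteness(self, immigration_death):
        part = hy.make_partition(immigration_death)
        for algorithm, runner in [("pure_ssa", hy.pure_ssa_run)]:
            tr = runner(immigration_death, _cfg(t_end=20.0, seed=3))
            assert np.all(tr.column("X") == np.round(tr.column("X")))
        for runner in (hy.hr_exact_run, hy.accelerated_run, hy.hrssa_run):
            tr = runner(immigration_death, part, _cfg(t_end=20.0, seed=3))
            assert np.all(tr.column("X") == np.round(tr.column("X")))

    def test_discrete_columns_stay_integral_in_hybrid_run(self, calcium_net):
        tr = hy.hr_exact_run(calcium_net, None,
                             _cfg(t_end=10.0, seed=1, output_points=101))
        for col in ("open", "close"):
            assert np.all(tr.column(col) == np.round(tr.column(col)))


class TestDynamicRun:
    def test_all_stochastic_thresholds_match_poisson_mean(self,
                                                          immigration_death):
        """Unreachable thresholds pin every reaction stochastic; the run is
        plain SSA and reproduces the stationary mean."""
        grid = np.arange(10.0, 10.0 + 3.0 * 1500, 3.0)
        cfg = hy.SimulationConfig(algorithm="dynamic", t_end=grid[-1],
                                  output_grid=grid, seed=13,
                                  lambda_prop=math.inf, n_substrate=0.0)
        tr = hy.dynamic_run(immigration_death, cfg)
        assert tr.meta["partition_changes"] == 0
        x = tr.column("X")
        se = x.std(ddof=1) / math.sqrt(len(x))
        assert abs(x.mean() - 10.0) < 3 * se

    def test_zero_thresholds_equal_pure_ode(self, immigration_death):
        cfg = _cfg(t_end=5.0, seed=0, output_points=21,
                   lambda_prop=0.0, n_substrate=0.0)
        dyn = hy.dynamic_run(immigration_death, cfg)
        ode = hy.pure_ode_run(immigration_death, cfg)
        assert dyn.meta["n_events"] == 0
        # same trajectory up to solver accuracy (the dynamic loop breaks the
        # integration at fluctuation-interval exits, the pure run does not)
        np.testing.assert_allclose(dyn.values, ode.values,
                                   rtol=1e-4, atol=1e-6)

    def test_ramping_rates_trigger_repartition_and_keep_the_mean(self):
        """Propensities sweep from slow to fast, so the partition must
        change; linear rates make E[X](t) = k_ramp*(t - 1 + exp(-t))
        independent of the interpretation."""
        net = fx.make_ramping_immigration(k_ramp=20.0, k_out=1.0)
        t_end = 3.0
        expected = 20.0 * (t_end - 1.0 + math.exp(-t_end))
        cfg = _cfg(t_end=t_end, seed=17, output_points=4,
                   lambda_prop=10.0, n_substrate=0.0, runs=300)
        cfg.algorithm = "dynamic"
        avg, traces = hy.run_ensemble(net, cfg)
        assert any(tr.meta["partition_changes"] >= 1 for tr in traces)
        finals = np.array([tr.column("X")[-1] for tr in traces])
        se = finals.std(ddof=1) / math.sqrt(len(finals))
        assert abs(finals.mean() - expected) < 3 * se + 1e-9

        cfg_ssa = hy.SimulationConfig(algorithm="pure_ssa", t_end=t_end,
                                      seed=17, output_points=4, runs=300)
        _, ssa_traces = hy.run_ensemble(net, cfg_ssa)
        ssa_finals = np.array([tr.column("X")[-1] for tr in ssa_traces])
        se2 = math.hypot(se, ssa_finals.std(ddof=1) / math.sqrt(len(ssa_finals)))
        assert abs(finals.mean() - ssa_finals.mean()) < 3 * se2


class TestTimedTransitions:
    def test_scheduled_single_firing(self):
        net = HybridPetriNet()
        net.add_place(Place("X", "discrete", 0))
        net.add_transition(Transition("pulse", "scheduled",
                                      schedule=(5.0, 0.0, 5.0)))
        net.add_arc("pulse", "X")
        tr = hy.pure_ssa_run(net, _cfg(t_end=10.0, seed=0,
                                       output_points=101))
        x = tr.column("X")
        assert x[tr.times < 5.0].max() == 0.0
        assert np.all(x[tr.times > 5.0] == 1.0)

    def test_scheduled_periodic_firings(self):
        net = HybridPetriNet()
        net.add_place(Place("X", "discrete", 0))
        net.add_transition(Transition("clock", "scheduled",
                                      schedule=(1.0, 1.0, 4.0)))
        net.add_arc("clock", "X")
        tr = hy.pure_ssa_run(net, _cfg(t_end=5.0, seed=0, output_points=11))
        assert tr.column("X")[-1] == 4.0

    def test_delay_fires_after_enabling(self):
        net = HybridPetriNet()
        net.add_place(Place("A", "discrete", 1))
        net.add_place(Place("B", "discrete", 0))
        net.add_transition(Transition("move", "deterministic_delay",
                                      delay=2.0))
        net.add_arc("A", "move")
        net.add_arc("move", "B")
        tr = hy.pure_ssa_run(net, _cfg(t_end=5.0, seed=0, output_points=51))
        b = tr.column("B")
        assert b[tr.times < 2.0].max() == 0.0
        assert np.all(b[tr.times > 2.1] == 1.0)

    def test_immediate_fires_before_stochastic_events(self):
        """An enabled immediate transition consumes its token at t=0,
        before any stochastic firing can see it."""
        net = HybridPetriNet(parameters={"k": 100.0})
        net.add_place(Place("A", "discrete", 1))
        net.add_place(Place("B", "discrete", 0))
        net.add_place(Place("C", "discrete", 0))
        net.add_transition(Transition("instant", "immediate"))
        net.add_transition(Transition(
            "slow", "stochastic",
            ex.Call("MassAction", (ex.Ref("k", "param"),))))
        net.add_arc("A", "instant")
        net.add_arc("instant", "B")
        net.add_arc("A", "slow")
        net.add_arc("slow", "C")
        tr = hy.pure_ssa_run(net, _cfg(t_end=1.0, seed=0, output_points=11))
        assert tr.column("B")[-1] == 1.0
        assert tr.column("C")[-1] == 0.0

    def test_immediate_conflict_weighted_frequencies(self):
        """Two immediates competing for one token, weights 1 and 3: the
        selection frequencies approach 1/4 and 3/4."""
        net = HybridPetriNet()
        net.add_place(Place("A", "discrete", 1))
        net.add_place(Place("L", "discrete", 0))
        net.add_place(Place("R", "discrete", 0))
        net.add_transition(Transition("left", "immediate", weight=1.0))
        net.add_transition(Transition("right", "immediate", weight=3.0))
        net.add_arc("A", "left")
        net.add_arc("left", "L")
        net.add_arc("A", "right")
        net.add_arc("right", "R")
        part = hy.Partition(frozenset(), frozenset(), frozenset(),
                            frozenset(net.places))
        eng = hy._Engine(net, part, _cfg(t_end=1.0), RandomStream(21, 0))
        n = 10_000
        wins = 0
        a_idx = eng.place_index["A"]
        r_idx = eng.place_index["R"]
        for _ in range(n):
            eng.x[a_idx] = 1.0
            before = eng.x[r_idx]
            eng.run_immediates(0.0)
            wins += int(eng.x[r_idx] - before)
        se = math.sqrt(0.25 * 0.75 / n)
        assert abs(wins / n - 0.75) < 3 * se

    def test_immediate_quiescence_guard(self):
        net = HybridPetriNet()
        net.add_place(Place("A", "discrete", 1))
        net.add_transition(Transition("loop", "immediate"))
        net.add_arc("A", "loop")
        net.add_arc("loop", "A")  # re-enables itself forever
        with pytest.raises(mdl.NetError, match="quiesce"):
            hy.pure_ssa_run(net, _cfg(t_end=1.0))


class TestEnsembles:
    def test_single_run_average_is_the_run(self, immigration_death):
        cfg = _cfg(t_end=5.0, seed=4, runs=1, output_points=21)
        cfg.algorithm = "pure_ssa"
        avg, traces = hy.run_ensemble(immigration_death, cfg)
        assert len(traces) == 1
        np.testing.assert_array_equal(avg.values, traces[0].values)

    def test_worker_count_does_not_change_the_result(self, immigration_death):
        base = dict(t_end=5.0, seed=4, runs=6, output_points=21)
        cfg1 = hy.SimulationConfig(algorithm="pure_ssa", workers=1, **base)
        cfg2 = hy.SimulationConfig(algorithm="pure_ssa", workers=3, **base)
        avg1, _ = hy.run_ensemble(immigration_death, cfg1)
        avg2, _ = hy.run_ensemble(immigration_death, cfg2)
        np.testing.assert_array_equal(avg1.values, avg2.values)

    def test_transient_mean_matches_birth_death_moment_equation(
            self, immigration_death):
        """1,000-run mean of X(10) vs the transient closed form
        10*(1 - exp(-10))."""
        cfg = hy.SimulationConfig(algorithm="pure_ssa", t_end=10.0, seed=19,
                                  runs=1000, output_points=2)
        avg, traces = hy.run_ensemble(immigration_death, cfg)
        finals = np.array([tr.column("X")[-1] for tr in traces])
        expected = 10.0 * (1.0 - math.exp(-10.0))
        se = finals.std(ddof=1) / math.sqrt(len(finals))
        assert abs(finals.mean() - expected) < 3 * se
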