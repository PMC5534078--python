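# Methods

`hpnsim` simulates biochemical reaction networks written as generalised
hybrid Petri nets (GHPN): places are species (discrete token counts or
continuous concentrations), transitions are reactions (stochastic,
continuous, immediate, deterministically delayed, or scheduled), and six
arc kinds (standard, read, inhibitor, equal, reset, modifier) connect
them.  Transition rates follow the *bio-semantics* convention: the
modeller supplies the kinetic rate law (e.g. mass action) as an
expression, and the same expression serves both the stochastic and the
deterministic regime.

## The hybrid simulation model

A *partition* splits the rate-bearing reactions into a stochastic (slow)
set and a deterministic (fast) set.  Species classes follow: a species is
continuous iff it is declared continuous or written by any deterministic
reaction — a species manipulated by both regimes must be continuous, and
discrete species are written only by the stochastic regime.  The
deterministic regime induces the ODE system

    dy_i/dt = sum_k s_ik * v_k(y, d),

where `s` is the stoichiometry of the deterministic reactions, `v_k`
their rates, and `d` the discrete marking frozen for the current
integration span.  Each slow reaction j has propensity `a_j(x)`; at
constant propensity its waiting time is exponential.

### Exact jump-equation synchronisation (`hr_exact`)

With propensities varying along the ODE flow, the next slow firing time
tau solves the jump equation

    integral_t^{t+tau} sum_j a_j(x(s)) ds = -log r,    r ~ U(0,1).

The implementation augments the ODE state with the accumulator
`g' = sum_j a_j(x)` and hands the solver the terminal event
`g + log r = 0` (increasing direction; the integrand is non-negative).
At the root, reaction j fires with probability `a_j(x(tau)) / sum a(x(tau))`
— propensities evaluated at the event time, which is what makes the
interpretation exact — its stoichiometry is applied, `g` resets, and the
solver is reinitialised.  When the model has **no continuous species** the
integrand is piecewise constant, the jump equation collapses to
`tau = -log(r)/a0`, and the loop is executed as the plain direct method
(identical draws, so the two code paths replay the same event stream from
the same random stream).  When the partition has **no slow reactions** the
run is a plain span-wise integration identical to the pure deterministic
mode.

### Accelerated synchronisation (`accelerated`)

The waiting time is taken in closed form, `dt = -log(r) / sum_j a_j(x)`,
with propensities evaluated at the state after the previous event (this
pins down the evaluation point the closed form needs; the choice is
recorded here because the approximation is only exact when slow
propensities do not read continuous species).  Slow reactions are
classified *dependent* (their firing changes a continuous species or a
species some deterministic rate reads) or *independent*; only dependent
firings reinitialise the ODE solver.  The per-run reinitialisation counter
is exposed in `Trace.meta["reinit_count"]` — it is the observable
mechanism behind the accelerated methods' speed-ups, and the package's
tests assert the exact-method counter equals the event count while the
accelerated counters vanish on all-independent models.

### Rejection-based synchronisation (`hrssa`)

Each tracked species gets a *fluctuation interval*
`[x(1-delta), x(1+delta)]`, widened to at least `x ± floor` for discrete
species and to at least `x ± delta` for continuous species near zero (a
point interval would otherwise signal an exit on any motion).  Interval
arithmetic over the rate expressions yields propensity bounds
`a̲_j <= a_j <= ā_j` valid while the state stays inside the interval;
enabledness over the interval is resolved in tri-state (definitely /
possibly / not enabled), with possibly-disabled reactions getting a zero
lower bound.  Candidate firings arrive as a Poisson stream of rate
`sum ā_j`; the candidate is drawn proportionally to `ā_j`, auto-accepted
when `u*ā_j <= a̲_j` (squeeze test — it changes no distribution, only the
number of exact-state evaluations), otherwise accepted iff
`u*ā_j <= a_j(x(t))` against the exact integrated state.  A rejected
candidate draws a fresh exponential budget (distribution-preserving
either way).  The ODE solver integrates with exit events at the interval
edges; an exit merely rebuilds the interval and the bounds — it never
reinitialises the solver, and accepted firings reuse the accelerated
dependent/independent rule.

### Dynamic partitioning (`dynamic`)

The hrssa loop, with the partition recomputed at every
fluctuation-interval exit: a reaction goes deterministic iff its current
propensity is at least `lambda_prop` **and** every substrate
(standard/read input place) holds at least `n_substrate`; reactions with
a `partition_hint` are pinned.  A repartition that changes any class
rebuilds the ODE system and reinitialises; a species reverting from
continuous to discrete class is rounded to the nearest integer (the
paperless corner of the scheme — rounding is standard practice in
dynamically partitioned simulators and keeps discrete invariants intact).

### Pure modes, timed kinds, ensembles

`pure_ssa` runs the Gillespie direct method over every rate-bearing
reaction (it requires integer initial markings); `pure_ode` integrates
all of them deterministically.  Immediate transitions fire before
anything else at a time point, repeatedly to quiescence (bounded at 10^4
firings), with conflicts resolved proportionally to their weights;
scheduled transitions fire at `start, start+interval, ..., <= end`; a
delay transition is booked `delay` after it becomes enabled at a span
boundary and cancelled if later found disabled.  Simultaneous work is
ordered immediate > scheduled/delayed > stochastic with ties broken by
transition id, so replays are deterministic.  Ensembles derive run *i*'s
generator as `PCG64(SeedSequence((seed, i)))`, which makes the averaged
trace bit-identical for any worker count.

## Expressions, bounds and compilation

Rates, guards and arc weights share one AST (literals, parameter and
place references, `+ - * / ^`, unary minus, comparisons and boolean
connectives for guards, `MassAction(k)` expanding to
`k * prod(input place ^ arc weight)` over the transition's standard/read
inputs, in sorted-place order so arc declaration order is irrelevant).
Discrete mass action uses the plain product `x^w`; a per-transition
`combinatorial` flag switches to the falling-factorial form
`k * x(x-1).../w!` for exact-CME work — the plain product is the default
because the same rate law must serve both regimes.  Interval bounds are
computed by straightforward interval arithmetic: exact for products of
non-negative monomials, valid but possibly loose for non-monotone
expressions, which is all the rejection machinery requires.  Hot paths
(propensities, ODE right-hand sides, binding guards) evaluate through
generated Python lambdas; the tree-walk interpreter remains the reference
implementation, and the two routes are property-tested against each
other.

## Coloured nets and unfolding

Colour sets are finite integer ranges and products of ranges (a 2-D grid
is `[1..w] x [1..h]`).  A coloured transition carries variables over
ranges and a boolean guard; each guard-satisfying total assignment (a
binding) becomes one flat transition named `base__v1_v2...`, and each
(place, colour) pair becomes a flat place `base__c1_c2...` — a
collision-free, reversible scheme that the view regexes rely on.
Enumeration backtracks over the variables in declaration order, pruning a
branch as soon as interval arithmetic proves the guard false on it, and
decides the innermost two variables in one vectorised guard evaluation
over their value grid; for a 4-neighbour diffusion guard over a 100x100
grid this visits ~10^4 interior nodes instead of 10^8 leaves.  Arc colour
expressions evaluating outside the place's colour set are a hard error
naming the transition and binding (silent wrapping or clamping would
corrupt a diffusion topology); the guard must exclude such bindings, as
the spatial calcium model's diffusion guard `(u-x)^2 + (v-y)^2 = 1` does.
An `all` colour expression on a read/modifier arc broadcasts the arc over
every colour, and a bare coloured-place reference in the rate then
expands to the sum over the place's instances — how the calcium inflow
reads "the total number of open channels" while unfolding to exactly one
instance (its other arcs are constant).

## Numerical choices

* ODE integration uses `scipy.integrate.solve_ivp` with dense output and
  terminal events: BDF for the `stiff` setting (default), RK45 for
  `nonstiff`; defaults `rtol = 1e-6`, `atol = 1e-9`.  Any integrator
  offering adaptive stepping, dense output and root finding could be
  dropped in behind the `Integrator` front-end.
* Each span is a fresh solver instance; the *reinitialisation counter*
  models the multistep-history discard semantics (what a warm CVODE-style
  solver would avoid), which is the quantity the accelerated methods
  optimise and the tests observe.
* Continuous markings that go slightly negative from round-off are
  clamped to zero when above `-10*atol`; larger negatives raise, since
  they indicate a genuine solver failure rather than round-off.
* Output is sampled onto a fixed uniform grid (default 1,000 points) from
  the dense solver output plus the latest discrete marking; a grid point
  coinciding with an event records the pre-event state.  Fixed grids are
  what make ensemble averaging and byte-stable CSV export possible.
* Uniform draws exclude 0 so `log r` is always finite.  The draw
  discipline is fixed (one uniform for the waiting time, then one for the
  selection) so that algorithms that coincide mathematically also replay
  identical event streams from a shared stream.

## Fixtures and what the tests do (and do not) show

All test models are generated programmatically:

* **Single-channel calcium** — a two-state channel (`k_open`, `k_close`)
  gating a continuous pool (`dCa/dt = k_in*open - k_pump*Ca`).  Stationary
  ensemble mean `k_in*p_open/k_pump`, `p_open = k_open/(k_open+k_close)`,
  from the first-moment equation of the linear hybrid system.
* **Coloured spatial calcium** — `n` channels in one cluster feeding cell
  `(cx, cy)` of a `w x h` grid, per-cell pumps, and one diffusion
  transition over variables `(x, y, u, v)` guarded to 4-neighbour pairs.
  At the reference configuration (3 channels, 100x100, cluster (50,50))
  it unfolds to 10,006 places (6 discrete) and 49,607 transitions
  (6 stochastic; 39,600 diffusion instances, one inflow).
* **Immigration-death** (`k_in`, `k_out`) — stationary law
  Poisson(`k_in/k_out`): mean = variance = `k_in/k_out`; transient mean
  `(k_in/k_out)(1 - e^{-k_out t})`.
* **Decay** — `X(t) = X0 e^{-kt}`; **A<->B** — `A+B` invariant;
  **independent-hybrid** — immigration-death beside an uncoupled
  continuous decay (every stochastic reaction independent);
  **coupled-hit** — a slow reaction with propensity `k_c Y(t)`,
  `Y(t) = y0 e^{-kt}`, whose first jump time has the closed form
  `tau = -log(1 - (-log r) k/(k_c y0))/k`; **ramping-immigration** — an
  immigration rate driven by a deterministically growing species, so
  propensities sweep across the dynamic-partitioning threshold while the
  linear moment equation `E[X](t) = k_ramp (t - 1 + e^{-t})` holds under
  every interpretation.

Rate constants in the calcium models are free parameters with repository
defaults chosen for order-unity event rates; they are not calibrated to
any particular cell type.  The generators emulate the *structure* of
multiscale biochemical models — gating, transport, diffusion, scale
separation — with linear or mass-action kinetics throughout, because
linearity is what provides exact moment references.  Passing tests
therefore demonstrate correctness of the algorithms (exactness on
pure-stochastic models, agreement with closed forms, conservation,
reinitialisation accounting, reproducibility); they do not exercise stiff
nonlinear kinetics, large dependent stochastic regimes, or parameter
regimes of any published cell-signalling model.

Problem sizes used in the checked claims: stationary moments use 10^4
samples of one long trajectory spaced three relaxation times apart
(burn-in ten relaxation times); the hybrid first-moment check uses 2,000
runs per parameter set with the tail half of a 30-time-unit window
averaged per run; grid conservation runs an 8x8 grid; the shared-stream
equivalence run covers ~10^3 events.  The statistical assertions use
three standard errors of the measured quantity.

## Known limitations

* Only integer-range and product colour sets exist; enumerated-symbol
  sets are a straightforward extension hook.  Reset and equal arcs are
  restricted to discrete places (ill-defined on reals).
* The accelerated method is an approximation whenever slow propensities
  read continuous species; the exact method is the reference there.
* SBML support is the L2V4 subset without rules, events, constraints or
  function definitions; reversible kinetic laws must be a top-level
  difference to be split.  The text dialect is compatible in spirit, not
  byte-compatible, with the ANDL family used by Petri net analysis tools
  (their grammars are unpublished); the grammar here ships in
  `docs/andl.md`.
* No tau-leaping or next-reaction variants, no DAEs/delays/sensitivities,
  no symbolic Jacobians.
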