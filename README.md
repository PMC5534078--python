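# hpnsim

Construction and hybrid stochastic/deterministic simulation of (coloured)
hybrid Petri net models of biochemical reaction networks.

Many cellular processes span scales: a handful of ion channels or gene
copies switch stochastically while the pools they gate — calcium,
transcripts, metabolites — evolve smoothly.  Simulating everything with
Gillespie's stochastic simulation algorithm (SSA) is exact but drowns in
fast events; pure ODE integration is fast but erases the fluctuations
that drive the biology.  `hpnsim` is for modellers who want both: models
are written as *generalised hybrid Petri nets* — discrete and continuous
places (species), five transition kinds (reactions), six arc kinds —
partitioned into a stochastic and a deterministic regime, and executed
with exact, accelerated, rejection-based or dynamically partitioned
hybrid algorithms.  Spatial or repetitive models are written once as
*coloured* nets and unfolded automatically.

## The algorithms

Given a partition with slow propensities `a_j(x)` and a deterministic
regime inducing `dy/dt = S v(y, d)`:

* **Exact jump equation** (`hr_exact`) — the next slow firing time τ
  solves `∫_t^{t+τ} Σ_j a_j(x(s)) ds = −log r`, integrated alongside the
  ODEs with root detection; the firing reaction is chosen ∝ `a_j(x(τ))`
  and the solver restarts after every event.
* **Accelerated** (`accelerated`) — waiting times in closed form,
  `Δτ = −log r / Σ_j a_j(x)`; stochastic reactions are classified
  dependent/independent, and only dependent firings restart the solver.
  Exact whenever slow propensities do not read continuous species.
* **Rejection-based** (`hrssa`) — per-species fluctuation intervals give
  propensity bounds `a̲_j ≤ a_j ≤ ā_j`; candidates arrive at rate `Σ ā_j`
  and are accepted with probability `a_j(x)/ā_j` (squeeze test first), so
  the deterministic regime is interrupted only at candidate times or
  interval exits.
* **Dynamic** (`dynamic`) — the hrssa loop with state-driven
  repartitioning by propensity and substrate-count thresholds.
* **Pure modes** (`pure_ssa`, `pure_ode`) — everything stochastic
  (direct method) or everything deterministic.

All algorithms share timed-transition handling (immediate, delayed,
scheduled kinds), a fixed output grid, and reproducible multi-run
ensembles (run *i* draws from `PCG64(SeedSequence((seed, i)))`, so
results are byte-identical for any worker count).  Models round-trip
through a documented plain-text dialect (`docs/andl.md`) and an SBML
L2V4 subset.

## Worked example

The bundled single-channel calcium model: a channel flips between
*close* and *open* (stochastic, rates `k_open·close`, `k_close·open`);
while open, calcium flows in at `k_in·open` and is pumped out at
`k_pump·Ca` (continuous).  With the repository defaults
(`k_open = k_close = 0.5`, `k_in = 2`, `k_pump = 1`) the stationary
ensemble mean of Ca is `k_in·p_open/k_pump = 2·0.5/1 = 1.0`.

```sh
$ hpnsim fixtures single-channel-calcium --output fig1.andl
$ hpnsim simulate fig1.andl --algorithm hr-exact --t-end 50 --runs 200 \
      --seed 1 --solver nonstiff --output fig1.csv
hpnsim INFO algorithm=hr_exact seed=1 runs=200 events=4957 reinits=4957
hpnsim INFO wrote fig1.csv (1000 rows, 3 columns)
```

`fig1.csv` holds the 200-run average of `close`, `open` and `Ca` on a
1,000-point grid.  The event count is the number of channel flips summed
over runs; `reinits` equals it because every flip changes the state the
ODE reads, so the exact method restarts the solver each time (the
accelerated counter would be 0 on a model whose firings leave the
continuous regime untouched).  Averaging the trace tail confirms the
closed form:

```python
>>> from hpnsim import views
>>> tr = views.read_csv("fig1.csv")
>>> tr.column("Ca")[tr.times >= 25].mean()
0.9984...   # stationary mean, analytic value 1.0
```

The coloured spatial version (three channels in a cluster feeding a
100×100 diffusion grid) unfolds with

```sh
$ hpnsim fixtures coloured-calcium --output calcium.candl
$ hpnsim unfold calcium.candl
places: 10006
transitions: 49607
  Ca_inflow: 1
  Ca_pump: 10000
  ch_close: 3
  ch_open: 3
  diffuse: 39600
```

— one flat place per (species, colour), one flat transition per
guard-satisfying binding: 39,600 diffusion instances (the directed
4-neighbour pairs of the grid), one inflow instance (its arc colours are
constant), and a pump per cell.

The same machinery is available as a library:

```python
from hpnsim import fixtures, hybrid

net = fixtures.make_single_channel_calcium()
cfg = hybrid.SimulationConfig(algorithm="hrssa", t_end=50.0, seed=1)
trace = hybrid.run_simulation(net, cfg)
```

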