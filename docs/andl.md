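# The hpnsim text dialect (.andl / .candl)

A line-oriented, human-readable notation for hybrid Petri nets, stable
under `parse_andl(write_andl(net)) == net`.  Comments run from `#` to end
of line; statements end with `;`.

## Flat documents (.andl)

```
hybrid net calcium

constants:
  k_open = 0.5;
  k_in = 2;

places:
  discrete:
    close = 1;
    open = 0;
  continuous:
    Ca = 0;

transitions:
  stochastic:
    ch_open:
      [close - 1] [open + 1]
      rate: MassAction(k_open);
  continuous:
    Ca_inflow:
      [open ~ 1] [Ca + 1]
      rate: k_in * open;
```

* Sections: `constants:`, `places:` (sub-blocks `discrete:` /
  `continuous:`), `transitions:` (one sub-block per transition kind:
  `stochastic:`, `continuous:`, `immediate:`, `deterministic_delay:`,
  `scheduled:`).
* A transition starts with `name:`; following lines hold its arcs and
  clauses.
* Arcs are bracketed `[place MARKER weight]` with markers

  | marker | arc kind                   |
  |--------|----------------------------|
  | `-`    | standard input (consumes)  |
  | `+`    | standard output (produces) |
  | `?`    | read (test >= weight)      |
  | `!`    | inhibitor (test < weight)  |
  | `=`    | equal (test == weight)     |
  | `0`    | reset (place := 0)         |
  | `~`    | modifier (rate access only)|

* Clauses: `rate: <expr>;` (stochastic/continuous), `delay: <t>;`,
  `schedule: (start, interval, end);`, `weight: <w>;` (immediate
  conflict weight), `hint: stochastic|deterministic;` (partition
  override), `combinatorial;` (falling-factorial mass action).

## Expressions

Identifiers resolve against declared constants, places and (coloured
dialect) variables.  Operators `+ - * / ^` (power right-associative),
unary minus, comparisons `< <= > >= = !=`, boolean `and`/`or`/`not` (or
`& | !`) in guards, calls `MassAction(k)`.

## Coloured documents (.candl)

```
coloured hybrid net spatial_calcium

colorsets:
  chCS = [1..3];
  X = [1..100];
  Y = [1..100];
  Grid2D = X x Y;

variables:
  m : chCS;
  x : X;  y : Y;  u : X;  v : Y;

places:
  discrete:
    closed : chCS = 1;
  continuous:
    Ca : Grid2D = 0 { (50, 50) = 1.5 };

transitions:
  stochastic:
    ch_open:
      vars: m;
      [closed{m} - 1] [open{m} + 1]
      rate: MassAction(k_open);
  continuous:
    diffuse:
      vars: x, y, u, v;
      [Ca{x, y} - 1] [Ca{u, v} + 1]
      guard: (u - x) ^ 2 + (v - y) ^ 2 = 1;
      rate: MassAction(D);
    Ca_inflow:
      [open{all} ~ 1] [Ca{50, 50} + 1]
      rate: k_in * open;
```

* `colorsets:` declares integer ranges `[lo..hi]` and products `A x B`.
* `variables:` declares colour variables over range sets; a transition
  lists the ones it binds (in binding order) in its `vars:` clause.
* Arc colour expressions sit in braces, one per component of the place's
  colour set; `{all}` broadcasts a read/modifier arc over every colour,
  and a bare place name in the rate then means the sum over all
  instances.
* Optional per-colour initial-marking overrides follow the default in
  braces: `{ (50, 50) = 1.5 3 = 2 }` (tuple keys for product sets,
  integers for ranges).

Unfolding maps `(place, colour)` to `place__c1_c2...` and
`(transition, binding)` to `transition__v1_v2...` (no suffix for
variable-free transitions).
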