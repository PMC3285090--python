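# Methods

## Model

`stemca` implements an on-lattice, agent-based (cellular-automaton) model of
early solid tumor growth under the cancer stem cell (CSC) hypothesis.  Two
cell types live on a fixed 2-D square lattice in which each site holds at
most one cell:

* **CSCs** are immortal and have unlimited replicative potential.  When a
  CSC divides it does so *symmetrically* with probability `p_s`, producing a
  second CSC, and otherwise *asymmetrically*, producing a non-stem daughter.
* **Non-stem cancer cells (CCs)** carry a remaining proliferative capacity
  ρ.  A first-generation CC inherits ρ = `rho_max` from the asymmetric
  division that created it; every CC division yields two CCs at the parent's
  ρ − 1 (both parent and daughter decrement).  A CC at ρ = 0 dies on its
  next division decision, vacating its site.

Each cell takes at most one action per time step `dt_h` (1 h).  A single
uniform draw is partitioned into a proliferation band of width
`dt_h / cell_cycle_h` (= 1/24: one division attempt per day on average), a
migration band of width `mu * dt_h / 24` (`mu` one-site hops per day), and a
quiescence remainder.  Proliferation and migration both require at least one
vacant adjacent site; a cell without vacant space is quiescent regardless of
its draw.  This spatial gating is the load-bearing mechanism of the model:
it applies to death as well, so a ρ = 0 CC enclosed on all sides is dormant
(quiescent and immortal) until space opens next to it.  Daughters and
migration targets are drawn uniformly from the vacant adjacent sites.

The update is asynchronous: each step visits every cell alive at the start
of the step exactly once, in a freshly shuffled random order, against the
current lattice state (sites freed by earlier deaths in the same step are
available to later cells); daughters born during a step first act in the
next step.  The lattice boundary is treated as permanently occupied (no
wraparound); the engine logs a warning when any cell touches the boundary.

A run seeds one CSC at the center of a 350 × 350 lattice (site width
10 μm) and advances until the population reaches `max_cells` (50,000) or
simulated time reaches `max_time_h` (5 years).  Total and CSC counts are
recorded weekly (168 h), always including t = 0 and the termination
instant, so threshold-crossing times resolve to the hour.

## Parameters

| name | meaning | default | notes |
| --- | --- | --- | --- |
| `rho_max` | CC generational life span | 5 | swept 0-10 |
| `p_s` | symmetric CSC division probability | 0.01 | 0.01 or 0.10 in the reference sweep |
| `mu` | migration speed, sites (cell widths)/day | 5 | 0, 5, 10, 15 in the reference sweep |
| `cell_cycle_h` | cell cycle time (h) | 24 | division-attempt rate 1/day |
| `dt_h` | time step (h) | 1 | partition must satisfy `dt/cc + mu*dt/24 <= 1` |
| `lattice_size` | lattice side (sites) | 350 | 50,000 cells fit with margin |
| `max_cells` | population stop | 50,000 | |
| `max_time_h` | time stop (h) | 43,800 | 5 years ≈ 260.7 weeks |
| `record_interval_h` | sampling interval (h) | 168 | weekly |
| `neighborhood` | adjacency stencil | `moore` | `vonneumann` available |

## Design choices where the design was open

* **Neighborhood.**  "Adjacent space" is implemented as the Moore (8-site)
  neighborhood by default, with von Neumann (4-site) exposed as
  configuration.  Moore makes one migration event correspond naturally to
  one cell width of displacement and is the common choice in this model
  family.  The choice is *not* neutral: von Neumann traps cells far more
  strongly, and in our measurements slows growth by roughly 20% at low
  `rho_max` and by a factor ~2 at `rho_max` = 9-10.  Under the Moore default
  the optimum `rho_max` at (`p_s` = 0.10, `mu` = 5) sits at 5 in a flat
  basin (rho 3-7 within ~1.5 weeks of each other) rather than 3, and deep
  hierarchies (`rho_max` ≥ 9) progress faster than under the 4-site rule.
* **Event exclusivity.**  One action per cell per step via a single
  partitioned draw (proliferation band first).  The partition keeps the
  total event probability ≤ 1 for every supported parameter set.
* **Death gating.**  A ρ = 0 CC dies only when it both has vacant adjacent
  space and draws a proliferation decision (the space check precedes the
  division decision).  Fully enclosed exhausted cells are therefore dormant,
  which produces the interior dormancy and peripheral death/renewal balance
  characteristic of the self-metastatic growth regime.
* **Update order.**  Asynchronous with a fresh per-step permutation, which
  avoids the write conflicts of synchronous updating.
* **Seeds.**  One `numpy` `default_rng` stream per run.  Replicates use
  `base_seed + i`; sweeps assign seeds cell-major, replicate-minor
  (`base_seed + cell_index * n + replicate`), so any subset of a sweep is
  reproducible in isolation.
* **Implementation.**  The event rules are compiled once as numba kernels;
  the per-operation wrappers call the same kernels.  As a pure optimisation,
  the per-cell action uniform is drawn before the neighborhood scan and the
  scan is skipped when the draw lands in the quiescence band; the per-visit
  outcome distribution is identical to checking space first, because a cell
  without vacant space ends quiescent whatever it draws.  Shuffle and action
  uniforms are generated in bulk per step for the same reason.

## Summary statistics

`time_to_threshold` reports the earliest sampled time at which a run's
population reaches a threshold; runs that hit the 5-year bound first are
*censored* at ~260.7 weeks.  Censored replicates are excluded from mean ±
SEM time statistics (SEM = sd/√n, ddof = 1) and counted separately.  Per
(`mu`, `p_s`) pair, the optimum `rho_max` minimizes the mean uncensored
time-to-threshold (ties toward smaller `rho_max`), and `t_critical` is that
minimum mean.  "CSC fraction at the optimum" is measured at run termination;
late-time fractions sit on a pseudo-steady plateau, so the precise
measurement time matters little.  Sizes "at t_critical" use the weekly
sample nearest `t_critical`, with already-terminated runs holding their
final size.  The summary table picks, per pair, the flanking (`rho_max`
below/above the optimum) pair whose mean sizes at `t_critical` match most
closely — tumors of similar size whose CSC content differs by orders of
magnitude.

## Validation oracles

`reference_oracle` shares no event-rule code with the engine:
`max_clone_population` expands the CC division tree exhaustively (peak
census 2^ρ) and bounds the engine's clone sizes from above;
`enclosed_dormancy_check` verifies that a fully packed micro-lattice
produces no events at all; `migration_rate_estimate` Monte-Carlo samples
the action partition directly and must agree with engine hop counts to
within binomial error.

## Problem sizes used in the tests and the acceptance script

Fast-regime growth-time checks use the reference protocol (n = 10
replicates to 50,000 cells).  The optimum-`rho_max` scan uses n = 5 per
`rho_max` value; the slowest parameter cells (`p_s` = 0.01) use n = 3-4.
Property checks that sweep `rho_max` (monotone CSC fraction, interior
minimum of growth time) run at scaled-down stopping sizes of 8,000-10,000
cells, where both properties are already established; the dormancy plateau
check stops at 5,000 cells, well past the CSC-fraction plateau for
non-migratory `rho_max` = 0 tumors.  These sizes are the package's own
choices for routine verification; any of them can be raised to the full
protocol through `SimulationParameters`.

## What the model does and does not capture

The model isolates the interplay of proliferation, migration, quiescence,
and capacity-limited death in a homogeneous 2-D environment.  It contains
no nutrient or oxygen fields, no mechanical forces, no angiogenesis, no
treatment, and no 3-D geometry; simulated times are therefore comparable
across parameter sets but are not calibrated to clinical growth curves.
Stochastic variability is large at small population sizes — ensembles
seeded by a single CSC with rare symmetric division (`p_s` = 0.01) show
order-of-magnitude spread in early sizes (founder effects), which is why
size-at-fixed-week statistics carry large SEMs.

## Known limitations

* The unstated adjacency/update conventions of the reference model are a
  genuine degree of freedom: quantities dominated by deep-hierarchy
  trapping (growth times at `rho_max` ≥ 9, the exact optimum `rho_max` at
  `p_s` = 0.10, `mu` = 5) shift materially between the Moore and von
  Neumann variants, while composition statistics (CSC fractions) are robust
  to the choice.
* Long runs at `mu` ≥ 5 can bring rare far-migrating cells into contact
  with the lattice boundary (logged as a warning); boundary sites behave as
  occupied, slightly constraining growth near the edge.
* `occupancy_count` conservation, CSC monotonicity, capacity bounds, and
  seed determinism are enforced by tests, not by runtime assertions in the
  hot loop.
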