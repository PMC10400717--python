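# frontsim

Agent-based simulation of developing neural morphologies: neurons grow,
migrate and prune in a shared 3D volume, under strict collision detection,
either serially (bit-reproducible) or on several CPU cores communicating
purely through shared memory.

## Who this is for

Computational neuroscientists who want to *grow* neurons instead of wiring
static morphologies: to study how physical interaction and competition
between expanding cells — no two structures may overlap — shapes dendritic
trees, migration paths and early connectivity.

## The model

A neuron is a tree of **fronts**: a spherical soma plus cylindrical neurite
segments (capsules: an axis segment with a radius).  Time advances in
discrete **cycles**; each cycle, every active front runs its subclass's
`manage_front` rule, which may

- **extend** (one child front), **branch** (two tapered children) or
  **terminate** — the classic growth-cone repertoire;
- **migrate** (somata only, before dendrites): optionally led by a
  filipodium climbing a diffusible substrate cue and leaving a trailing
  axon;
- **retract** a terminal front or an entire branch (applied serially at the
  end of the cycle);
- form **synapses** with nearby fronts (weights, Hebbian updates).

A new structure is rejected (`CollisionError`) whenever its capsule
overlaps an existing front, i.e. when the segment–segment distance
`d(s1, s2) < r1 + r2`.  Collision testing is restricted to nearby fronts by
a uniform lattice with spacing `grid_step` (default 20 µm): each front is
registered at the lattice points whose cells its axis touches, and a query
scans those points plus their 26 neighbours — provably equivalent to a
brute-force all-pairs sweep when `r1 + r2 < grid_step`.

With `num_cores > 2` the engine runs workers as forked processes sharing
fixed-size arrays split into private per-core sections; grid updates are
arbitrated by a serial lock broker with single-holder read locks and
two-stage (preliminary → full) write locks, and lock timeouts surface as
`GridCompetitionError` for the model to retry.  Serial runs (`num_cores=2`)
are deterministic for a fixed seed; parallel runs are only statistically
equivalent.

## Worked example

The bundled stochastic growth model: a 10 µm soma sprouts 5 dendritic roots
(ends 15 µm from the centre), and each dendrite front then extends one 5 µm
segment within a 20° cone with probability 0.94 or branches into two
tapered children with probability 0.06, until its path length reaches
100 µm.

```bash
frontsim run random --seed 1 --cycles 25 --db trace.db
```

prints one line per cycle and a summary:

```
cycle 1: 6 live fronts
cycle 2: 11 live fronts
...
cycle 24: 157 live fronts
cycle 25: 157 live fronts
final: 157 live fronts, 157 created
```

Cycle 1 creates the soma's 5 roots (6 live fronts including the soma);
growth then adds roughly one front per active tip per cycle, branches fork
new tips, and the count plateaus when every tip passes the 100 µm bound.
Because branching is probabilistic the final size varies strongly between
seeds (≈100–270 fronts).  Then:

```bash
frontsim stats trace.db          # grid occupancy metrics
frontsim export-swc trace.db out # one standard SWC file per neuron
frontsim resume trace.db --cycles 10 --out longer.db
```

`stats` reports the occupancy measures of the collision grid (mean grid
points used per front, fraction of lattice points occupied, fractions of
occupied points holding 1–5 and 1–10 fronts, and the maximum number of
fronts at one point).  Running the same serial command twice produces
byte-identical databases and SWC files.

The same models are available from Python:

```python
from frontsim import models
sim = models.run_random_growth(seed=1, n_cycles=25, num_cores=5)  # 4 workers
print(sim.store.live_count())
sim.destruction()
```

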