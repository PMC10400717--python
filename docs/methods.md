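# Methods

## Model and assumptions

The simulator grows neurons as trees of *fronts*: a spherical soma and
cylindrical neurite segments, each represented as a capsule (axis segment
plus radius).  Fronts are agents: once per cycle every enabled front runs
its subclass's `manage_front` rule.  A cycle is an abstract unit of
developmental time (of order 1–100 h); no physical time conversion is made.
Growth is purely phenomenological — no forces, no mechanics — with a single
hard physical constraint: no two fronts may overlap.  Two capsules overlap
when the minimum distance between their axis segments is smaller than the
sum of their radii; exact touching is not an overlap, and the comparison
carries a 1e-9 µm guard band so round-off cannot flag touching pairs.

Structural contact is not collision.  A child's origin coincides with its
parent's attachment point, sibling branches share a branch-point anchor, and
a trailing-axon segment ends on its soma's surface; collision testing
therefore skips the candidate's parent and any front whose endpoint
coincides with the candidate's anchor, and the migration check skips the
soma's filipodium and the children still anchored on its surface.  Detached
pieces of a soma's own axon are obstacles like anything else.

### Geometry conventions

* A soma has a single coordinate `orig` (its centre), branch order 0 and
  path length 0; cylinders have `orig` and `end`.
* A child of a cylinder starts at the parent's `end`.  A child of a soma is
  anchored on the soma surface, on the ray from the centre to the requested
  position: a position 15 µm from the centre of a 10 µm soma yields a 5 µm
  root.  Positions inside the parent raise `InsideParentError`.
* `path_length(child) = path_length(parent) + |end − orig|`; `order`
  increments by one at every attachment (somata are the only order-0
  fronts).
* `taper(r, f) = r·f` (default factor 0.9) thins dendrites at branch
  points; a single multiplicative factor is the minimal contract that keeps
  repeated application strictly decreasing.
* Cone sampling (`unit_heading_sample`) is uniform in solid angle on the
  spherical cap: cos θ ~ U[cos θmax, 1], azimuth uniform.  Uniformity in
  solid angle (rather than in angle) was chosen because it is the unique
  rotation-symmetric density on the cap.
* Candidate branching directions (`unit_branching_sample`) are uniform on
  the sphere, rejected until all pairwise separations reach 180°/n degrees
  (default), so that several of the n candidates usually survive collision
  testing; infeasible demands fail with `SamplingError` after a bounded
  number of draws.

## Collision grid

The volume is covered by a lattice with spacing `grid_step` (default
20 µm); lattice points are keyed by a positive integer `gid`.  A front is
registered at every lattice point whose (closed) cubic cell intersects the
axis-aligned bounding box of its axis, pruned to points within
(√3/2)·`grid_step` of the axis.  This rule guarantees that the nearest
lattice point of *any* point on the axis is registered.  Consequently, for
two colliding capsules with `r1 + r2 < grid_step`, the nearest lattice
points of the two closest axis points differ by less than two cells per
axis — i.e. by at most one — so scanning a candidate's gids plus their 26
neighbours finds every colliding partner and the grid query is exactly
equivalent to a brute-force all-pairs sweep.  Fronts thicker than
`grid_step/2` emit a configuration warning because the proof (and the
method) assumes fronts comparable to or smaller than the lattice spacing.

Registrations are stored as linked blocks (default 10 entries): `grid[gid]`
points at the first block in a flat `grid_extra` array; a full block's last
slot converts into a link to a freshly allocated block, moving the entry
that occupied it.  Deregistration back-fills the hole with the chain's last
entry so entries stay contiguous.  Blocks are allocated from per-writer
private sections; freed chains are recycled only in the single-writer
(serial) map — a cross-writer free list would itself need locking, so the
shared-memory map deliberately leaks empty blocks (memory is cheap at the
20 000-front default scale).

Scan order (ascending gid, then block order) fixes which collider a
first-hit query reports, which keeps serial runs bit-reproducible.

## The engine

Each cycle: the clock increments; enabled fronts are dispatched in category
order — growing, then migrating, then other active — ascending FrontID
within each category; retractions queued during the cycle are applied
serially at the end (flags set, tree unlinked, grid deregistered, dead
synapses closed); the cycle's events are committed to the SQLite trace in a
single transaction; and the schedule for the next cycle is rebuilt from the
status flags.  All engine errors (`CollisionError`, `InsideParentError`,
`VolumeError`, `GridCompetitionError`, `OverflowError`, `NotSelfError`)
leave state unchanged, so models may treat a failed attempt as free and
retry.  Methods that mutate a front may only be called by the front being
processed (`NotSelfError` otherwise); newly created fronts are active and
growing from the next cycle.

`solve_collision` probes up to 8 alternative positions at the failed step
length, deflected 30–120° away from the colliding front (and ±45/90° out of
plane), returning the first collision-free one or None.  It is a
convenience heuristic, not part of the collision guarantee.

Soma migration keeps the filipodium's tip fixed and re-anchors its origin
on the new surface (the filipodium leads; the soma follows), and deposits
one trailing-axon segment from the previous axon tip to the new soma
surface.  That segment spans space the soma just vacated (the deposit is
skipped if the soma moved less than its radius), so it is registered
without a collision check; with the default demo parameters (4 µm step,
5 µm soma, 0.8 µm axon) the chord always lies inside the soma's swept
volume.

## Shared-memory parallel engine

Core 1 is the admin; cores 2..N are forked worker processes.  All mutable
state lives in fork-shared fixed-size arrays split into N equal private
sections — a writer allocates records only in its own slice but reads
anywhere — so record creation needs no locks at all; exhausting a section
raises `OverflowError` naming the array to enlarge.  Workers poll the
shared clock, fetch front IDs from two per-worker instruction slots
(clearing a slot acknowledges receipt; the admin keeps both filled while
the backlog is large and sends single IDs near exhaustion, then a sentinel),
run `manage_front` under a per-(seed, worker, cycle) random stream, and
stream symbol-coded results into a per-worker mailbox the admin drains.
Retractions are applied by the admin, serially, at end of cycle.

Grid access is the one shared mutable structure.  A serial lock broker
(run interleaved with the admin's scheduling loop; a dedicated broker core
buys nothing) grants:

* **read locks** — single holder per gid, allowed under a preliminary write
  lock but not a full one;
* **write locks** — two stages: a preliminary claim (positive gid request)
  and a full lock (negated gid, grantable only to the preliminary holder
  once no reader remains).  Holders release by zeroing their entry;
  re-requesting a held lock is an idempotent success.

A request not granted within `lock_timeout` raises
`GridCompetitionError`.  The default timeout is 1 s; the bundled models run
with 0.05 s because on few cores a long wait per competition event costs
more than the retry it replaces.  Deadlock is impossible in the hot path
(single-gid locks, no hold-and-wait) and timeouts bound every other wait.

Two mechanisms prevent same-cycle overlaps:

1. *Scheduling avoidance*: before dispatching a front the admin puts
   preliminary write locks on the front's grid points and defers fronts
   whose points are locked by another worker, so cores tend not to grow in
   the same region simultaneously.
2. *Register-then-recheck*: `add_child` collision-checks lock-free, then
   registers the new front (brief per-gid preliminary→full locks around
   each write), then re-runs the collision check.  For two racing
   overlapping candidates, whichever registration completes second starts
   its recheck after the first is visible, so at least one of the pair
   aborts (rolls back its registration and raises `CollisionError`); an
   overlapping pair can never persist to the end of a cycle.  Both may
   abort and retry — wasteful but safe.

This differs from holding read locks during collision detection: lock-free
reads can transiently miss an entry that a concurrent *deregistration* is
moving (the back-fill step).  Deregistration during a cycle happens only in
soma migration and filipodium relocation; the growth-only models that the
parallel engine is exercised with never deregister mid-cycle, and the
migration demo runs serially.  This residual window is a known limitation.

Parallel runs make no reproducibility promise (scheduling depends on OS
timing); the seed fully determines serial runs, including byte-identical
trace databases and SWC exports.  Statistical equivalence of serial and
parallel growth is part of the test suite (rank-sum test on front-count
distributions over 20 seeds, α = 0.01).

## Storage

The SQLite trace is event-sourced with one transaction per committed cycle
(a `cycles` table marks commits, so a truncated file is detected): front
creations store full geometry and tree links, retractions set a death cycle
(rows are never deleted), migrations append to a history table and refresh
the soma row, and synapses, substrate deposits and per-front attribute
values get their own tables.  `import_simulation` rebuilds the full
in-memory state (store, tree links in insertion order, grid registrations,
counters, flags) from a compatible database and continues appending; it is
a serial-mode feature.  SWC export writes the standard 7 columns, sample 1
being the soma (type 1) and each live cylinder contributing one sample at
its `end` with its parent's sample index; retracted fronts are omitted.

## Fixture models

**Random growth** (`run_random_growth`): soma radius 10 µm, 10 candidate
directions, 5 roots with ends 15 µm from the centre, dendrite radius 2 µm
(a plausible proximal-dendrite calibre; thinner than the soma and under the
`grid_step/2` soundness bound), extension probability 0.94 within a 20°
cone at 5 µm per step, branching probability 0.06 into two children tapered
by 0.9 from 4 candidate directions, termination at a 100 µm path length, in
a 200³ µm volume.  Extensions inherit the parent radius; tapering applies
only at branch points.  Collision failures retry with a new direction (cap
100); grid-competition failures postpone the event to the next cycle after
2–3 attempts, since a new random direction lands in the same grid cell and
cannot help.  A run completes in ≈21–26 cycles; final size varies strongly
across seeds (≈100–270 fronts) because branching is probabilistic.

**Migration demo** (`migration_demo`): five substrate point sources
(10⁸ molecules each, D = 25 µm²/cycle) in a 120³ µm box; each soma (5 µm)
sprouts a 0.6 µm filipodium and a trailing axon, the filipodium re-aims
each cycle toward the highest Poisson-sampled concentration among 7
candidates in a 60° cone, the soma steps up to 4 µm/cycle toward the tip,
and when the sampled count reaches 1500 (reached within roughly 15–30 µm of
a source under these parameters) the filipodium retracts, migration stops
and a few dendrites grow.  The concentration of a source is the
instantaneous point-source diffusion kernel
C(r,t) = n·(4πDt)^{−3/2}·exp(−r²/4Dt) with t in cycles since deposit
(t = 0 read as 1), summed over sources; the stochastic sample is
Poisson(C·v) with a 1 µm³ probe volume — the simplest closed form with the
right qualitative behaviour (spread, dilution, shot noise).  The kernel is
transient, so the stopping threshold is a scene parameter, not a library
constant.

**Retraction demo** (`retraction_demo`): a neuron grows 8 straight radial
dendrites of 3 segments; presynaptic boutons (0.3 µm-gap spheres standing
in for axonal side branches) are placed to give the dendrites a prescribed
synapse count pattern (default 0,1,2,3,4,5,6,9); on the pruning cycle every
dendrite whose branch carries fewer than 5 synapses is retracted in one
cycle.

## What the synthetic models do and do not show

The fixtures exercise every engine mechanism — growth, collision handling,
migration, retraction, synapses, substrate, both engines — at the scale of
single or few neurons with printed, analytically checkable parameters.
They do not emulate real morphometry (no branch-order statistics fitted to
data, no layer-specific rules, no forests of hundreds of cells), so passing
tests validate the simulation machinery and its invariants, not the
biological realism of any particular grown tree.

## Numerical and size choices

* Segment–segment distance: the classic closest-point parameterisation
  with clamping, special-cased for degenerate (point) segments; validated
  against a dense-sampling oracle to 1e-3 µm.
* Default capacities: 20 000 fronts, grid blocks of 10, 2 000 synapses and
  substrate sources; all raise `OverflowError` naming the array.
* Test and acceptance problem sizes — 150–500-front collision scenes,
  20-seed batches, 26-cycle runs — were chosen so the full suite exercises
  every criterion in a few minutes on one core while keeping every
  statistical check adequately powered (e.g. ≥2 000 Bernoulli draws for the
  0.94 extension fraction).
* The watchdog in the parallel admin (60 s without any scheduling, result
  or grant progress) turns a hypothetical wedge into a diagnosable error
  rather than a hang.

## Known limitations

* No progenitor proliferation, tissue expansion, diameter growth after
  creation, or live plotting.
* The shared map never reclaims grid blocks (see above).
* Lock-free collision reads can transiently miss entries while a
  concurrent deregistration back-fills (relevant only to parallel
  migration-style models; see the parallel section).
* `import_simulation` of a database written by a multi-worker run is not
  supported for synapse/substrate tables whose ids exceed the admin
  section; resume serially.
* Synapse duplicate detection is a linear scan and races are tolerated in
  parallel mode (synapses do not occupy space, so no geometric invariant is
  at stake).
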