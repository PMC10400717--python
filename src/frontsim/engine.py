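"""The simulation core: the admin object, neuron seeding, the cycle loop,
growth/migration/retraction methods and the error taxonomy glue.

Control flow per cycle: the clock is incremented, every enabled front is
dispatched to its ``manage_front`` rule — growing fronts first, then
migrating ones, then other active fronts, each category in ascending FrontID
order so serial runs are bit-reproducible — the retractions queued during
the cycle are applied serially at the end, the cycle's events are committed
to the trace database in one transaction, and the scheduling registries are
rebuilt from the status flags.

With ``num_cores=2`` (one admin plus one processing core) the engine runs
serially in-process and is deterministic for a fixed seed; with more cores
the shared-memory parallel engine (:mod:`frontsim.parallel`) takes over and
individual runs are no longer reproducible, only statistically equivalent.
"""

from __future__ import annotations

import contextlib
import math

import numpy as np

from . import environment, fronts, geometry, grid, storage
from .errors import (CollisionError, GridCompetitionError, NotSelfError,
                     OverflowError, UsageError, VolumeError)
from .fronts import (FLAG_ACTIVE, FLAG_AXON_FRONT, FLAG_FILIPODIUM,
                     FLAG_GROWING, FLAG_MIGRATING, FLAG_RETRACTED,
                     FLAG_TRAILING_AXON, SHAPE_CYLINDER, SHAPE_SPHERE,
                     _I_AXON_TIP, _I_FILI, _I_FLAGS, _I_SHAPE, Front, FrontID,
                     FrontStore, attach_child, collect_branch,
                     make_child_geometry, mark_retracted, pack_id, unpack_id)


class _NullLockRegion:
    def upgrade(self, gids):
        pass


class NullLocker:
    """Lock interface used by the serial engine: everything is a no-op.

    ``needs_postcheck`` tells the engine whether a second collision check
    after grid registration is required; with a single writer the answer is
    no.
    """

    needs_postcheck = False

    @contextlib.contextmanager
    def write_region(self, gids):
        yield _NullLockRegion()

    @contextlib.contextmanager
    def read_region(self, gids):
        yield

    @contextlib.contextmanager
    def brief_write(self, gid):
        yield


class Constellation:
    """The execution context handed to every ``manage_front`` call.

    It exposes the clock, the volume, the random generator and all engine
    operations fronts may invoke on themselves.  Models receive it as the
    single argument of ``manage_front`` and pass it back into front methods.
    """

    def __init__(self, sim, pid=1, rng=None, locker=None, recorder=None):
        self.sim = sim
        self._pid = pid
        self.rng = rng if rng is not None else sim._rng
        self._locker = locker if locker is not None else NullLocker()
        self._record = recorder if recorder is not None \
            else sim._record_event
        self._current = None
        self.gce_count = 0

    # -- convenience views --------------------------------------------------
    @property
    def cycle(self):
        return self.sim.cycle

    @property
    def volume(self):
        return self.sim.grid_config.vmin, self.sim.grid_config.vmax

    @property
    def store(self):
        return self.sim.store

    def _check_self(self, front):
        if self._current is not None and front.id != self._current:
            raise NotSelfError(
                f"method called on {front.id} while processing "
                f"{self._current}")

    def _require_volume(self, *points):
        for p in points:
            if not self.sim.grid_config.contains(p):
                raise VolumeError(f"position {np.asarray(p)} is outside "
                                  "the simulation volume")

    # -- growth -------------------------------------------------------------
    def add_child(self, parent: Front, new_pos, radius=None, swc_type=None,
                  role=None):
        """Create a new front as a child of `parent` at `new_pos`.

        Collision-checked and atomic: on any error (Collision, InsideParent,
        Volume, GridCompetition, Overflow, NotSelf) no state changes.
        Returns the new front; it is active and growing from the next cycle.
        """
        self._check_self(parent)
        if radius is None:
            radius = parent.radius
        if radius <= 0:
            raise UsageError("child radius must be positive")
        orig, end, radius = make_child_geometry(parent, new_pos, radius)
        self._require_volume(orig, end)
        gids = grid.front_to_gids(orig, end, radius, self.sim.grid_config)
        store = self.sim.store
        row = parent._row
        if swc_type is None:
            if role == "axon":
                swc_type = 2
            elif role == "filipodium":
                swc_type = 7
            elif parent.is_sphere():
                swc_type = 3
            else:
                swc_type = parent.swc_type or 3
        # First collision check: authoritative in serial mode, a cheap
        # lock-free early abort in parallel mode.
        hit = grid.collision_query(
            store, self.sim.grid_map, orig, end, radius,
            exclude={pack_id(parent.id)}, mode="first", gids=gids,
            anchor=orig)
        if hit is not None:
            raise CollisionError(unpack_id(hit))
        idx = store.allocate(self._pid, row)
        fid = FrontID(row, idx)
        flags = FLAG_ACTIVE | FLAG_GROWING
        if role == "filipodium":
            flags |= FLAG_FILIPODIUM
        elif role == "axon":
            flags |= FLAG_AXON_FRONT
        store.init_front(fid, SHAPE_CYLINDER, orig, end, radius,
                         birth_cycle=self.cycle, swc_type=swc_type,
                         flags=flags)
        child = store.get_front(fid)
        attach_child(store, parent, child)
        self._register_with_rollback(gids, fid, parent, child)
        if self._locker.needs_postcheck:
            # Register-then-recheck makes same-cycle avoidance sound: of
            # two racing candidates, the later registration's recheck
            # necessarily sees the earlier one, so no overlapping pair can
            # survive (both may abort and retry; neither persists).
            hit = grid.collision_query(
                store, self.sim.grid_map, orig, end, radius,
                exclude={pack_id(parent.id), pack_id(fid)}, mode="first",
                gids=gids, anchor=orig)
            if hit is not None:
                self._rollback_child(gids, fid, child)
                raise CollisionError(unpack_id(hit))
        if role == "filipodium":
            store._i[parent._row][parent._idx, _I_FILI] = pack_id(fid)
        elif role == "axon":
            store._i[parent._row][parent._idx, _I_AXON_TIP] = pack_id(fid)
            if parent.is_sphere():
                store._i[parent._row][parent._idx, _I_FLAGS] |= \
                    FLAG_TRAILING_AXON
        self._record(("created", pack_id(fid)))
        return child

    def _register_with_rollback(self, gids, fid, parent, child):
        packed = pack_id(fid)
        done = []
        try:
            for g in gids:
                with self._locker.brief_write(g):
                    self.sim.grid_map.register(g, packed, self._pid)
                done.append(g)
        except (OverflowError, GridCompetitionError):
            self._rollback_child(done, fid, child, registered=True)
            raise

    def _rollback_child(self, gids, fid, child, registered=True):
        """Undo a child creation: deregister, unlink, clear the record and
        return the allocation slot (the caller's last allocation)."""
        packed = pack_id(fid)
        if registered:
            for g in gids:
                for attempt in range(5):
                    try:
                        with self._locker.brief_write(g):
                            self.sim.grid_map.deregister(g, packed)
                        break
                    except GridCompetitionError:
                        if attempt == 4:
                            # never leave a phantom registration behind
                            self.sim.grid_map.deregister(g, packed)
        fronts.unlink_child(self.sim.store, child)
        self.sim.store._i[fid.row][fid.index, :] = 0
        self.sim.store._counters[self._pid, fid.row] -= 1

    # -- migration ----------------------------------------------------------
    def migrate_soma(self, soma: Front, new_pos):
        """Move a soma to `new_pos` (collision-checked).

        Only somata that have not grown dendrites may migrate; a single
        leading filipodium and a trailing-axon chain are the allowed
        children.  With a trailing axon enabled, a new axon front spanning
        the vacated position is created automatically; a filipodium keeps
        its tip fixed and is re-anchored on the new soma surface.
        """
        self._check_self(soma)
        if not soma.is_sphere():
            raise UsageError("only somata migrate")
        new_pos = np.asarray(new_pos, dtype=float)
        self._require_volume(new_pos)
        store = self.sim.store
        i_row = store._i[soma._row]
        fili_packed = int(i_row[soma._idx, _I_FILI])
        axon_tip_packed = int(i_row[soma._idx, _I_AXON_TIP])
        allowed = {fili_packed, axon_tip_packed}
        for c in soma.children():
            if pack_id(c.id) not in allowed and not c.has_flag(
                    FLAG_AXON_FRONT) and not c.has_flag(FLAG_FILIPODIUM):
                raise UsageError(
                    "soma migration is limited to somata before they grow "
                    "dendrites")
        r = soma.radius
        cfg = self.sim.grid_config
        old_pos = soma.orig
        old_gids = grid.front_to_gids(old_pos, old_pos, r, cfg)
        new_gids = grid.front_to_gids(new_pos, new_pos, r, cfg)
        union = sorted(set(old_gids) | set(new_gids))
        # structural exclusions only: the soma itself, its filipodium, and
        # children still anchored on the current surface.  Detached pieces
        # of its own trailing axon are obstacles like anything else.
        exclude = {pack_id(soma.id), fili_packed}
        for c in soma.children():
            if (np.linalg.norm(c.orig - old_pos) <= r + 1e-6):
                exclude.add(pack_id(c.id))
        exclude.discard(0)
        packed_soma = pack_id(soma.id)
        with self._locker.write_region(union) as region:
            hit = grid.collision_query(
                store, self.sim.grid_map, new_pos, new_pos, r,
                exclude=exclude, mode="first", gids=new_gids)
            if hit is not None:
                raise CollisionError(unpack_id(hit))
            region.upgrade(union)
            for g in old_gids:
                self.sim.grid_map.deregister(g, packed_soma)
            soma.orig = new_pos
            soma.end = new_pos
            for g in new_gids:
                self.sim.grid_map.register(g, packed_soma, self._pid)
            axon_child = None
            if soma.has_flag(FLAG_TRAILING_AXON) and axon_tip_packed:
                axon_child = self._extend_trailing_axon(
                    soma, unpack_id(axon_tip_packed), new_pos)
            if fili_packed:
                self._reanchor_filipodium(soma, unpack_id(fili_packed),
                                          new_pos)
        self._record(("migrated", packed_soma))
        if axon_child is not None:
            self._record(("created", pack_id(axon_child.id)))
        return soma

    def _extend_trailing_axon(self, soma, tip_fid, new_centre):
        """Deposit one axon front from the old tip to the new soma surface.

        The geometry is structural (it spans space the soma just vacated),
        so no collision check is performed.
        """
        store = self.sim.store
        tip = store.get_front(tip_fid)
        orig = tip.end
        d = new_centre - orig
        dist = float(np.linalg.norm(d))
        if dist <= soma.radius + 1e-9:
            return None  # soma barely moved; no room for a new segment
        end = new_centre - d / dist * soma.radius
        gids = grid.front_to_gids(orig, end, tip.radius,
                                  self.sim.grid_config)
        idx = store.allocate(self._pid, tip._row)
        fid = FrontID(tip._row, idx)
        store.init_front(fid, SHAPE_CYLINDER, orig, end, tip.radius,
                         birth_cycle=self.cycle, swc_type=2,
                         flags=FLAG_AXON_FRONT)
        child = store.get_front(fid)
        attach_child(store, tip, child)
        packed = pack_id(fid)
        for g in gids:
            self.sim.grid_map.register(g, packed, self._pid)
        store._i[soma._row][soma._idx, _I_AXON_TIP] = packed
        return child

    def _reanchor_filipodium(self, soma, fili_fid, new_centre):
        """Keep the filipodium tip fixed; move its origin to the new soma
        surface (the filipodium leads the soma and persists ahead of it)."""
        store = self.sim.store
        fili = store.get_front(fili_fid)
        packed = pack_id(fili_fid)
        old_gids = grid.front_to_gids(fili.orig, fili.end, fili.radius,
                                      self.sim.grid_config)
        tip = fili.end
        d = tip - new_centre
        dist = float(np.linalg.norm(d))
        if dist <= soma.radius + 1e-9:
            return
        new_orig = new_centre + d / dist * soma.radius
        new_gids = grid.front_to_gids(new_orig, tip, fili.radius,
                                      self.sim.grid_config)
        for g in old_gids:
            self.sim.grid_map.deregister(g, packed)
        fili.orig = new_orig
        fili.path_length = float(np.linalg.norm(tip - new_orig))
        for g in new_gids:
            self.sim.grid_map.register(g, packed, self._pid)
        self._record(("relocated", packed))

    def relocate_end(self, front: Front, new_end):
        """Move a terminal front's end point (used by exploring filipodia).

        Collision-checked like growth; the front stretches in place instead
        of depositing a new segment.
        """
        self._check_self(front)
        if not front.is_cylinder():
            raise UsageError("only cylinder fronts can relocate their end")
        if not front.is_terminal():
            raise UsageError("only terminal fronts can relocate their end")
        new_end = np.asarray(new_end, dtype=float)
        self._require_volume(new_end)
        store = self.sim.store
        cfg = self.sim.grid_config
        packed = pack_id(front.id)
        old_gids = grid.front_to_gids(front.orig, front.end, front.radius,
                                      cfg)
        new_gids = grid.front_to_gids(front.orig, new_end, front.radius, cfg)
        union = sorted(set(old_gids) | set(new_gids))
        parent = front.parent
        exclude = {packed, pack_id(parent) if parent else 0}
        with self._locker.write_region(union) as region:
            hit = grid.collision_query(
                store, self.sim.grid_map, front.orig, new_end, front.radius,
                exclude=exclude, mode="first", gids=new_gids,
                anchor=front.orig)
            if hit is not None:
                raise CollisionError(unpack_id(hit))
            region.upgrade(union)
            for g in old_gids:
                self.sim.grid_map.deregister(g, packed)
            old_len = front.length()
            front.end = new_end
            front.path_length += front.length() - old_len
            for g in new_gids:
                self.sim.grid_map.register(g, packed, self._pid)
        self._record(("relocated", packed))
        return front

    # -- retraction ---------------------------------------------------------
    def retract(self, front: Front):
        """Queue removal of a terminal front (applied at end of cycle)."""
        self._check_self(front)
        if front.is_retracted():
            raise UsageError("front is already retracted")
        if not front.is_terminal():
            raise UsageError("single-front retraction requires a terminal "
                             "front; use retract_branch for subtrees")
        self._record(("retract", pack_id(front.id)))

    def retract_branch(self, front: Front, child: Front):
        """Queue removal of `child` and its whole subtree."""
        self._check_self(front)
        if child.parent != front.id:
            raise UsageError("retract_branch expects a direct child")
        if child.is_retracted():
            raise UsageError("branch is already retracted")
        self._record(("retract_branch", pack_id(child.id)))

    # -- status -------------------------------------------------------------
    def enable(self, front: Front, growing=True, migrating=False):
        self._check_self(front)
        flags = front.flags | FLAG_ACTIVE
        flags &= ~(FLAG_GROWING | FLAG_MIGRATING)
        if growing:
            flags |= FLAG_GROWING
        if migrating:
            flags |= FLAG_MIGRATING
        front._set_int(_I_FLAGS, flags)
        self._record(("flags", pack_id(front.id), flags))
        return front

    def disable(self, front: Front):
        self._check_self(front)
        flags = front.flags & ~(FLAG_ACTIVE | FLAG_GROWING | FLAG_MIGRATING)
        front._set_int(_I_FLAGS, flags)
        self._record(("flags", pack_id(front.id), flags))
        return front

    # -- collision recovery -------------------------------------------------
    def solve_collision(self, front: Front, new_pos, error, radius=None):
        """Try to find a collision-free alternative for a failed position.

        Up to 8 candidate positions at the same step length are tested,
        angularly deflected away from the colliding front in increasing
        steps.  Returns a position (numpy array) or None when every
        candidate collides.
        """
        self._check_self(front)
        if radius is None:
            radius = front.radius
        new_pos = np.asarray(new_pos, dtype=float)
        anchor = front.orig if front.is_sphere() else front.end
        step_vec = new_pos - anchor
        step_len = float(np.linalg.norm(step_vec))
        if step_len <= 0:
            return None
        u = step_vec / step_len
        collider = self.sim.store.get_front(error.collider)
        mid = (anchor + new_pos) / 2.0
        away = mid - (collider.orig + collider.end) / 2.0
        away = away - (away @ u) * u
        norm = float(np.linalg.norm(away))
        if norm < 1e-9:
            away = geometry._orthonormal_frame(u)[0]
        else:
            away = away / norm
        side = np.cross(u, away)
        cands = []
        for ang in (30.0, 60.0, 90.0, 120.0):
            a = math.radians(ang)
            cands.append(math.cos(a) * u + math.sin(a) * away)
        for ang in (45.0, 90.0):
            a = math.radians(ang)
            cands.append(math.cos(a) * u + math.sin(a) * side)
            cands.append(math.cos(a) * u - math.sin(a) * side)
        exclude = {pack_id(front.id)}
        if front.parent:
            exclude.add(pack_id(front.parent))
        for direction in cands[:8]:
            pos = anchor + direction * step_len
            try:
                orig, end, r = make_child_geometry(front, pos, radius)
                self._require_volume(orig, end)
                gids = grid.front_to_gids(orig, end, r, self.sim.grid_config)
            except Exception:
                continue
            with self._locker.read_region(gids):
                hit = grid.collision_query(
                    self.sim.store, self.sim.grid_map, orig, end, r,
                    exclude=exclude, mode="first", gids=gids, anchor=orig)
            if hit is None:
                return pos
        return None

    # -- environment --------------------------------------------------------
    def add_synapse(self, pre: Front, post: Front, weight=1.0,
                    max_distance=0.5):
        """Create a synapse between two nearby fronts (no space occupied)."""
        if self._current is not None and self._current not in (pre.id,
                                                               post.id):
            raise NotSelfError("add_synapse must be called by the pre or "
                               "post front being processed")
        table = self.sim.synapses
        environment.check_synapse(table, pre, post, max_distance)
        idx = table.add(self._pid, pack_id(pre.id), pack_id(post.id),
                        weight, self.cycle)
        self._record(("synapse", idx))
        return idx

    def secrete(self, front: Front, name, n_mol, diffusion):
        """Deposit substrate at the front's distal coordinate."""
        self._check_self(front)
        pos = front.orig if front.is_sphere() else front.end
        idx = self.sim.substrate.add(self._pid, name, pos, n_mol, diffusion,
                                     self.cycle)
        self._record(("substrate", idx))
        return idx

    def sample_concentration(self, point, stochastic=True):
        """Substrate concentration at `point` (Poisson count by default)."""
        self._require_volume(point)
        return environment.sample_concentration(
            point, self.sim.substrate.sources(), self.cycle, rng=self.rng,
            stochastic=stochastic)

    def count_synapses(self, front: Front, branch=False):
        ids = (collect_branch(self.sim.store, front) if branch
               else [front.id])
        return environment.count_synapses(self.sim.synapses, ids)


class Simulator:
    """The admin object: owns the store, grid, clock, storage and workers.

    Parameters mirror the usual anatomy of a growth script: the Front
    subclasses used (``front_classes``, one store row each), the simulation
    volume in um (two corners, or a single corner meaning [0,0,0]..corner),
    the number of cores (2 = admin + one processing core = serial,
    reproducible; more = shared-memory parallel), the trace database file,
    the random seed, and the grid/capacity tuning knobs.
    """

    def __init__(self, front_classes, volume, db_path=None, num_cores=2,
                 seed=0, grid_step=20.0, capacity=20_000, block_size=10,
                 grid_extra_capacity=None, synapse_capacity=2000,
                 substrate_capacity=2000, substrate_names=(),
                 lock_timeout=1.0, verbose=0):
        volume = np.asarray(volume, dtype=float)
        if volume.shape == (3,):
            vmin, vmax = np.zeros(3), volume
        else:
            vmin, vmax = volume[0], volume[1]
        if num_cores < 2:
            raise UsageError("the minimum number of cores is 2 "
                             "(admin + one processing core)")
        self.num_workers = num_cores - 1
        self.parallel = self.num_workers > 1
        num_sections = self.num_workers + 1
        shared = self.parallel
        self.seed = int(seed)
        self.lock_timeout = float(lock_timeout)
        self.verbose = verbose
        self.grid_config = grid.GridConfig(vmin, vmax, grid_step=grid_step,
                                           block_size=block_size)
        self.store = FrontStore(front_classes, capacity=capacity,
                                num_sections=num_sections, shared=shared)
        self.grid_map = grid.GridIndexMap(
            self.grid_config, extra_capacity=grid_extra_capacity,
            num_sections=num_sections, shared=shared)
        self.synapses = environment.SynapseTable(
            synapse_capacity, num_sections=num_sections, shared=shared)
        self.substrate = environment.SubstrateTable(
            substrate_capacity, num_sections=num_sections, shared=shared,
            names=substrate_names)
        self.cycle = 0
        self._rng = np.random.default_rng(self.seed)
        self._events = []
        self._retraction_queue = []
        self._neurons = []            # (neuron_id, soma FrontID, name)
        self._neuron_counter = 0
        self.front_count_log = []     # live fronts after each cycle
        self.gce_log = []             # per-cycle {pid: GridCompetition count}
        self._closed = False
        self.db_path = db_path
        self.db = storage.open_database(db_path if db_path else ":memory:")
        storage.write_meta(self.db, {
            "schema_version": storage.SCHEMA_VERSION,
            "seed": self.seed,
            "num_cores": num_cores,
            "grid_step": grid_step,
            "capacity": self.store.capacity,
            "volume_min": " ".join(str(v) for v in self.grid_config.vmin),
            "volume_max": " ".join(str(v) for v in self.grid_config.vmax),
        })
        storage.write_neuron_types(
            self.db, [c.__name__ for c in front_classes])
        self.constellation = Constellation(self)
        self._parallel_engine = None
        if self.parallel:
            from .parallel import ParallelEngine
            self._parallel_engine = ParallelEngine(self)

    # -- context management -------------------------------------------------
    def __enter__(self):
        return self

    def __exit__(self, *exc):
        self.destruction()

    def destruction(self):
        """Shut down workers, flush and close the trace database."""
        if self._closed:
            return
        if self._parallel_engine is not None:
            self._parallel_engine.shutdown()
        self.db.commit()
        self.db.close()
        self._closed = True

    # -- seeding ------------------------------------------------------------
    def add_neurons(self, front_class, name, n=1, placement=None,
                    soma_radius=10.0, origins=None, grid_spacing=None,
                    max_tries=100, swc_type=1):
        """Create `n` collision-checked somata of `front_class`.

        Placement: an explicit list of coordinates (``origins``), a bounding
        box ``placement=(corner_min, corner_max)`` for uniform random
        placement, or ``grid_spacing`` for a regular grid filling the
        placement box.  Somata are allocated in the admin's private section
        and become active (growing) on the next cycle.
        """
        row = self.store.row_for_class(front_class)
        positions = []
        if origins is not None:
            positions = [np.asarray(p, dtype=float) for p in origins]
            if len(positions) != n:
                raise UsageError("origins must list exactly n positions")
        elif placement is not None:
            lo = np.asarray(placement[0], dtype=float)
            hi = np.asarray(placement[1], dtype=float)
            if grid_spacing is not None:
                axes = [np.arange(lo[k], hi[k] + 1e-9, grid_spacing)
                        for k in range(3)]
                pts = (np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1)
                       .reshape(-1, 3))
                if len(pts) < n:
                    raise UsageError("placement grid has fewer points than "
                                     "requested neurons")
                positions = [pts[k] for k in range(n)]
            else:
                positions = None  # drawn per-soma below, with retries
                box = (lo, hi)
        else:
            raise UsageError("specify origins or a placement box")

        created = []
        for k in range(n):
            if positions is not None:
                front = self._place_soma(row, positions[k], soma_radius,
                                         swc_type)
            else:
                front = None
                last_error = None
                for _ in range(max_tries):
                    pos = self._rng.uniform(box[0], box[1])
                    try:
                        front = self._place_soma(row, pos, soma_radius,
                                                 swc_type)
                        break
                    except CollisionError as err:
                        last_error = err
                if front is None:
                    raise last_error
            self._neuron_counter += 1
            nid = self._neuron_counter
            nname = f"{name}_{k}" if n > 1 else name
            self._neurons.append((nid, front.id, nname))
            storage.write_neuron(self.db, nid, front.id, nname, self.cycle)
            created.append(front)
        return created

    def _place_soma(self, row, pos, radius, swc_type):
        pos = np.asarray(pos, dtype=float)
        if not self.grid_config.contains(pos):
            raise VolumeError(f"soma position {pos} outside the volume")
        gids = grid.front_to_gids(pos, pos, radius, self.grid_config)
        hit = grid.collision_query(self.store, self.grid_map, pos, pos,
                                   radius, mode="first", gids=gids)
        if hit is not None:
            raise CollisionError(unpack_id(hit))
        idx = self.store.allocate(1, row)
        fid = FrontID(row, idx)
        self.store.init_front(fid, SHAPE_SPHERE, pos, None, radius,
                              birth_cycle=self.cycle, swc_type=swc_type,
                              flags=FLAG_ACTIVE | FLAG_GROWING)
        packed = pack_id(fid)
        for g in gids:
            self.grid_map.register(g, packed, 1)
        self._events.append(("created", packed))
        return self.store.get_front(fid)

    def deposit_substrate(self, name, positions, n_mol, diffusion):
        """Deposit substrate point sources (admin-side, between loops)."""
        if name not in self.substrate.names:
            self.substrate.names.append(name)
        idxs = []
        for pos in positions:
            pos = np.asarray(pos, dtype=float)
            if not self.grid_config.contains(pos):
                raise VolumeError(f"substrate position {pos} outside volume")
            idx = self.substrate.add(1, name, pos, n_mol, diffusion,
                                     self.cycle)
            self._events.append(("substrate", idx))
            idxs.append(idx)
        return idxs

    def _record_event(self, event):
        self._events.append(event)

    # -- scheduling ---------------------------------------------------------
    def _schedule(self):
        """(growing, migrating, other) FrontID lists, ascending within each
        category."""
        growing, migrating, other = [], [], []
        for row in range(1, self.store.num_rows + 1):
            i = self.store._i[row]
            flags = i[:, _I_FLAGS]
            used = i[:, _I_SHAPE] != 0
            active = used & ((flags & FLAG_ACTIVE) != 0) \
                & ((flags & FLAG_RETRACTED) == 0)
            for idx in np.nonzero(active)[0]:
                f = int(flags[idx])
                fid = FrontID(row, int(idx))
                if f & FLAG_GROWING:
                    growing.append(fid)
                elif f & FLAG_MIGRATING:
                    migrating.append(fid)
                else:
                    other.append(fid)
        return growing, migrating, other

    # -- the cycle loop -----------------------------------------------------
    def simulation_loop(self, n_cycles):
        """Run `n_cycles` growth cycles; callable repeatedly."""
        if self._closed:
            raise UsageError("simulator already shut down")
        if self.parallel:
            return self._parallel_engine.run(n_cycles)
        for _ in range(int(n_cycles)):
            self.cycle += 1
            growing, migrating, other = self._schedule()
            con = self.constellation
            try:
                for fid in (*growing, *migrating, *other):
                    front = self.store.get_front(fid)
                    if not front.is_active():
                        continue  # e.g. retracted earlier this cycle
                    con._current = fid
                    front.manage_front(con)
            finally:
                con._current = None
                self._finish_cycle({1: con.gce_count})
                con.gce_count = 0
        return self

    def _finish_cycle(self, gce_by_pid=None):
        """Serial end-of-cycle work: retractions, storage, registries."""
        events = self._events
        self._events = []
        retract_events = [e for e in events if e[0] in ("retract",
                                                        "retract_branch")]
        applied = self._apply_retractions(retract_events)
        persist = [e for e in events
                   if e[0] not in ("retract", "retract_branch")]
        persist.extend(("retracted", p) for p in applied)
        persist.extend(self._events)  # synapse removals from retractions
        storage.write_cycle(self.db, self.cycle, persist, self.store,
                            synapses=self.synapses,
                            substrate=self.substrate)
        self._events = []
        self.front_count_log.append(self.store.live_count())
        self.gce_log.append(dict(gce_by_pid or {}))

    def _apply_retractions(self, retract_events):
        """Serially apply queued retractions: flag, unlink, deregister,
        drop dead synapses.  Returns packed ids actually retracted."""
        applied = []
        for ev in retract_events:
            fid = unpack_id(ev[1])
            front = self.store.get_front(fid)
            if front.is_retracted():
                continue  # queued twice in one cycle
            if ev[0] == "retract":
                targets = [fid]
            else:
                targets = collect_branch(self.store, front)
            # unlink the root of the removal from its parent, flag the rest
            for t in targets:
                f = self.store.get_front(t)
                if f.is_retracted():
                    continue
                packed = pack_id(t)
                gids = grid.front_to_gids(f.orig, f.end, f.radius,
                                          self.grid_config)
                mark_retracted(self.store, t, self.cycle)
                for g in gids:
                    self.grid_map.deregister(g, packed)
                applied.append(packed)
        if applied:
            dead = set(applied)
            for idx in self.synapses.live_indices():
                pre, post = self.synapses.endpoints(idx)
                if pack_id(pre) in dead or pack_id(post) in dead:
                    self.synapses.kill(idx, self.cycle)
                    self._events.append(("synapse_removed", idx))
        return applied

    # -- persistence --------------------------------------------------------
    def import_simulation(self, path):
        """Restore a previously written trace database into this engine.

        Must be called on a fresh simulator with the same Front subclass
        registry; continuing the run appends to the history.
        """
        if self.cycle != 0 or self.store.created_count() != 0:
            raise UsageError("import_simulation requires a fresh simulator")
        src = storage.open_database(path)
        try:
            data = storage.read_simulation(src)
        finally:
            src.close()
        names = [c.__name__ for c in self.store.front_classes]
        if data["neuron_types"] != names:
            raise UsageError(
                f"database neuron types {data['neuron_types']} do not match "
                f"this simulator's {names}")
        store = self.store
        attr_last = {}
        for r, idx, cyc, aname, value in data["attributes"]:
            attr_last[(r, idx, aname)] = value
        max_idx_per_row = {}
        for rec in data["fronts"]:
            (row, idx, prow, pidx, srow, sidx, ox, oy, oz, ex, ey, ez,
             radius, shape, order, path_length, birth, death, swc, flags,
             fili, axon_tip) = rec
            if idx > store.capacity:
                raise UsageError("database capacity exceeds this "
                                 "simulator's front capacity")
            fid = FrontID(row, idx)
            store.init_front(
                fid, shape, (ox, oy, oz), (ex, ey, ez), radius,
                parent=FrontID(prow, pidx) if pidx else None,
                soma=FrontID(srow, sidx), order=order,
                path_length=path_length, birth_cycle=birth, swc_type=swc,
                flags=flags)
            i = store._i[row]
            i[idx, fronts._I_DEATH] = death
            i[idx, _I_FILI] = fili
            i[idx, _I_AXON_TIP] = axon_tip
            cls = store.class_for_row(row)
            for k, aname in enumerate(cls.attributes):
                store._f[row][idx, fronts._N_FLOAT_BASE + k] = \
                    attr_last.get((row, idx, aname), 0.0)
            max_idx_per_row[row] = max(max_idx_per_row.get(row, 0), idx)
            # rebuild the child linked list in insertion order
            if pidx:
                parent = store.get_front(FrontID(prow, pidx))
                child = store.get_front(fid)
                saved = (path_length, order)
                attach_child(store, parent, child)
                store._f[row][idx, fronts._F_PATH] = saved[0]
                i[idx, fronts._I_ORDER] = saved[1]
            if not (flags & FLAG_RETRACTED):
                packed = pack_id(fid)
                for g in grid.front_to_gids((ox, oy, oz), (ex, ey, ez),
                                            radius, self.grid_config):
                    self.grid_map.register(g, packed, 1)
        # unlink retracted fronts from the rebuilt lists
        for rec in data["fronts"]:
            row, idx = rec[0], rec[1]
            flags = rec[19]
            if flags & FLAG_RETRACTED and rec[3]:
                with contextlib.suppress(UsageError):
                    fronts.unlink_child(store,
                                        store.get_front(FrontID(row, idx)))
        # section counters: highest used index per (section, row)
        for row in range(1, store.num_rows + 1):
            used = np.nonzero(store._i[row][:, _I_SHAPE] != 0)[0]
            for pid in range(1, store.num_sections + 1):
                start, endi = store.section_bounds(pid)
                inside = used[(used >= start) & (used <= endi)]
                store._counters[pid, row] = (
                    int(inside.max()) - start + 1 if len(inside) else 0)
        for nid, srow, sidx, nname, birth in data["neurons"]:
            self._neurons.append((nid, FrontID(srow, sidx), nname))
            storage.write_neuron(self.db, nid, FrontID(srow, sidx), nname,
                                 birth)
            self._neuron_counter = max(self._neuron_counter, nid)
        for rec in data["synapses"]:
            (sid, prow, pidx, porow, poidx, weight, birth, death) = rec
            while self.synapses._counters[1] < sid:
                idx = self.synapses.allocate(1)
            self.synapses.data[sid] = (pack_id(FrontID(prow, pidx)),
                                       pack_id(FrontID(porow, poidx)),
                                       weight, birth, death)
        for rec in data["substrate"]:
            sid, sname, x, y, z, n_mol, diff, birth = rec
            if sname not in self.substrate.names:
                self.substrate.names.append(sname)
            while self.substrate._counters[1] < sid:
                idx = self.substrate.allocate(1)
            self.substrate.data[sid] = (x, y, z, n_mol, diff, birth,
                                        self.substrate.names.index(sname))
        self.cycle = data["cycle"]
        return self

    # -- outputs ------------------------------------------------------------
    def neurons(self):
        return list(self._neurons)

    def export_swc(self, neuron_name, path):
        for nid, soma_fid, nname in self._neurons:
            if nname == neuron_name:
                return storage.export_swc(self.store, soma_fid, path,
                                          comment=f"neuron {nname}")
        raise UsageError(f"unknown neuron {neuron_name!r}")

    def stats(self):
        """Grid occupancy metrics over the current live fronts."""
        return grid.grid_stats(self.grid_map,
                               live_fronts=self.store.live_count())
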