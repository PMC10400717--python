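"""Shared-memory parallel engine: worker loops, private-section scheduling,
a results mailbox and the layered grid-locking protocol.

Layout.  All simulation state (front store, grid, synapse and substrate
tables) lives in fork-shared arrays partitioned into private writer
sections: core 1 is the admin, cores 2..N are workers.  The admin drives the
clock; workers poll it, fetch front IDs from their two instruction slots,
run ``manage_front`` and stream results (front ID + symbol records) into a
per-worker mailbox the admin consumes.

Locking.  Grid access is arbitrated by a lock broker that runs serially,
interleaved with the admin's other work.  Workers post a gid into their
private request slot and poll the lock table: read locks are single-holder
per gid and coexist with preliminary write locks but not full ones; write
locks are two-stage (preliminary -> full, the full request being the
negated gid from the current preliminary holder).  A request not granted
within the timeout raises GridCompetitionError.  While a front is scheduled
on a worker the admin preliminarily write-locks the front's grid points and
never co-schedules fronts whose points are already locked by another
worker.  During ``add_child`` the actual grid writes take brief per-gid
preliminary -> full locks; collision *reads* are lock-free, and same-cycle
safety comes from register-then-recheck (see ``Constellation.add_child``):
of two racing overlapping candidates, the one whose registration is later
necessarily sees the other in its recheck and aborts, so no overlapping
pair can ever persist.
"""

from __future__ import annotations

import time
from multiprocessing import Process, sharedctypes

import numpy as np

from . import _shm, grid
from .engine import Constellation
from .errors import GridCompetitionError, SimulationError
from .fronts import pack_id, unpack_id

SENTINEL = -1          # end-of-cycle instruction
SHUTDOWN = -1          # clock value signalling workers to exit

# result record codes
R_DONE = 1
R_CREATED = 2
R_MIGRATED = 3
R_RETRACT = 4
R_RETRACT_BRANCH = 5
R_FLAGS = 6
R_SYNAPSE = 7
R_SUBSTRATE = 8
R_RELOCATED = 9
R_ERROR = 10
R_GCE = 11
R_CYCLE_DONE = 12

_EVENT_TO_CODE = {
    "created": R_CREATED,
    "migrated": R_MIGRATED,
    "retract": R_RETRACT,
    "retract_branch": R_RETRACT_BRANCH,
    "flags": R_FLAGS,
    "synapse": R_SYNAPSE,
    "substrate": R_SUBSTRATE,
    "relocated": R_RELOCATED,
}
_CODE_TO_EVENT = {v: k for k, v in _EVENT_TO_CODE.items()}

RESULT_CAPACITY = 8192


class LockTables:
    """The four shared lock arrays of the grid protocol.

    ``read_lock``/``write_lock`` are indexed by gid (0 = unlocked; a write
    entry of +pid is a preliminary lock, -pid a full lock).  ``rreq`` and
    ``wreq`` hold one pending request per core: a positive gid (read or
    preliminary write) or, in ``wreq``, a negated gid for the full-lock
    upgrade.  Only the broker writes grants; holders release by zeroing
    their own lock entry; requesters own their request slot.
    """

    def __init__(self, n_gids, max_pid, shared=False):
        self.n_gids = n_gids
        self.max_pid = max_pid
        self.read_lock = _shm.zeros(n_gids + 1, "int32", shared)
        self.write_lock = _shm.zeros(n_gids + 1, "int32", shared)
        self.rreq = _shm.zeros(max_pid + 1, "int32", shared)
        self.wreq = _shm.zeros(max_pid + 1, "int32", shared)


def lock_broker_step(tables: LockTables):
    """One serial pass of the lock broker over all request slots.

    Grants whatever can be granted now; ungrantable requests stay pending.
    Returns the number of grants issued.
    """
    grants = 0
    read_lock = tables.read_lock
    write_lock = tables.write_lock
    for pid in range(2, tables.max_pid + 1):
        g = int(tables.rreq[pid])
        if g > 0:
            w = int(write_lock[g])
            if int(read_lock[g]) == pid:        # re-entrant: already held
                tables.rreq[pid] = 0
            elif int(read_lock[g]) == 0 and w >= 0:
                # free, and not under *full* write lock (preliminary is OK)
                read_lock[g] = pid
                tables.rreq[pid] = 0
                grants += 1
        g = int(tables.wreq[pid])
        if g > 0:
            w = int(write_lock[g])
            if w == pid:                        # re-entrant preliminary
                tables.wreq[pid] = 0
            elif w == 0:
                write_lock[g] = pid
                tables.wreq[pid] = 0
                grants += 1
        elif g < 0:
            gid = -g
            w = int(write_lock[gid])
            if w == -pid:                       # re-entrant full
                tables.wreq[pid] = 0
            elif w == pid:
                # upgrade by the current preliminary holder, once no reader
                # (other than the requester itself) is on the gid
                r = int(tables.read_lock[gid])
                if r == 0 or r == pid:
                    write_lock[gid] = -pid
                    tables.wreq[pid] = 0
                    grants += 1
            # a full request without holding the preliminary stays pending
    return grants


def acquire_with_timeout(tables: LockTables, pid, gid, mode, timeout=1.0,
                         pump=None, clock=time.monotonic, sleep=time.sleep):
    """Post a lock request and wait for the broker's grant.

    mode is "read", "prelim" or "full".  ``pump`` (if given) is called while
    waiting and should run the broker — used in serial tests and by the
    logical-clock harness; in the real engine the admin pumps the broker.
    Raises GridCompetitionError on timeout; if the grant lands in the
    cancellation window it is accepted instead.
    """
    read_lock = tables.read_lock
    write_lock = tables.write_lock
    if mode == "read":
        if int(read_lock[gid]) == pid:
            return True
        req, slot, want = gid, tables.rreq, pid
        table = read_lock
    elif mode == "prelim":
        if int(write_lock[gid]) == pid:
            return True
        req, slot, want = gid, tables.wreq, pid
        table = write_lock
    elif mode == "full":
        if int(write_lock[gid]) == -pid:
            return True
        req, slot, want = -gid, tables.wreq, -pid
        table = write_lock
    else:
        raise ValueError(f"unknown lock mode {mode!r}")
    slot[pid] = req
    deadline = clock() + timeout
    pause = 5e-5
    while True:
        if pump is not None:
            pump()
        if int(table[gid]) == want:
            return True
        if clock() >= deadline:
            break
        sleep(pause)
        pause = min(pause * 1.5, 2e-3)
    # timed out: withdraw the request, then accept a grant that raced in
    slot[pid] = 0
    if pump is not None:
        pump()
    else:
        sleep(5e-3)
    if int(table[gid]) == want:
        return True
    raise GridCompetitionError(gid)


def release_lock(tables: LockTables, pid, gid, mode):
    """Release a held lock by zeroing the holder's entry."""
    if mode == "read":
        if int(tables.read_lock[gid]) == pid:
            tables.read_lock[gid] = 0
    else:
        w = int(tables.write_lock[gid])
        if w == pid or w == -pid:
            tables.write_lock[gid] = 0


class _LockRegion:
    def __init__(self, locker, gids):
        self.locker = locker
        self.gids = gids

    def upgrade(self, write_gids):
        for g in write_gids:
            self.locker._acquire(g, "full")


class GridLocker:
    """Worker-side lock plumbing used by the engine's growth operations.

    ``brief_write(gid)`` is the hot path: a two-stage preliminary -> full
    write lock held only across a single grid write, then released.
    ``write_region(gids)`` preliminarily locks the gids plus their
    neighbourhood for the duration of a check+write window (used by the
    rarer migration/relocation operations); ``upgrade`` converts the target
    gids to full locks just before the actual grid writes.  ``read_region``
    takes plain read locks for read-only queries.  On GridCompetitionError
    every lock already held by the operation is released before the error
    propagates, and the constellation's per-cycle error counter is bumped.
    """

    needs_postcheck = True

    def __init__(self, tables, config, pid, timeout=1.0, pump=None,
                 constellation=None):
        self.tables = tables
        self.config = config
        self.pid = pid
        self.timeout = timeout
        self.pump = pump
        self.constellation = constellation
        self._held_write = []
        self._held_read = []

    def _acquire(self, gid, mode):
        try:
            acquire_with_timeout(self.tables, self.pid, gid, mode,
                                 timeout=self.timeout, pump=self.pump)
        except GridCompetitionError:
            if self.constellation is not None:
                self.constellation.gce_count += 1
            raise
        if mode == "read":
            self._held_read.append(gid)
        elif mode == "prelim":
            self._held_write.append(gid)
        # a full lock upgrades an already-tracked preliminary entry

    def _release_all(self):
        for g in self._held_write:
            release_lock(self.tables, self.pid, g, "write")
        for g in self._held_read:
            release_lock(self.tables, self.pid, g, "read")
        self._held_write = []
        self._held_read = []

    def write_region(self, gids):
        return _RegionContext(self, gids, write=True)

    def read_region(self, gids):
        return _RegionContext(self, gids, write=False)

    def brief_write(self, gid):
        return _BriefWriteContext(self, gid)


class _BriefWriteContext:
    """Preliminary -> full write lock on one gid, held very briefly."""

    def __init__(self, locker, gid):
        self.locker = locker
        self.gid = gid
        self._had_prelim = False

    def __enter__(self):
        locker = self.locker
        # remember whether the scheduling layer already holds this gid for
        # us, so we do not release the admin's lock on exit
        self._had_prelim = (int(locker.tables.write_lock[self.gid])
                            == locker.pid)
        try:
            acquire_with_timeout(locker.tables, locker.pid, self.gid,
                                 "prelim", timeout=locker.timeout,
                                 pump=locker.pump)
            acquire_with_timeout(locker.tables, locker.pid, self.gid,
                                 "full", timeout=locker.timeout,
                                 pump=locker.pump)
        except GridCompetitionError:
            if locker.constellation is not None:
                locker.constellation.gce_count += 1
            w = int(locker.tables.write_lock[self.gid])
            if w == locker.pid and not self._had_prelim:
                locker.tables.write_lock[self.gid] = 0
            raise
        return self

    def __exit__(self, exc_type, exc, tb):
        w = int(self.locker.tables.write_lock[self.gid])
        if w == -self.locker.pid:
            if self._had_prelim:
                # restore the scheduler's preliminary hold
                self.locker.tables.write_lock[self.gid] = self.locker.pid
            else:
                self.locker.tables.write_lock[self.gid] = 0
        return False


class _RegionContext:
    def __init__(self, locker, gids, write):
        self.locker = locker
        self.gids = gids
        self.write = write

    def __enter__(self):
        region = grid.search_region(self.gids, self.locker.config)
        try:
            for g in region:
                self.locker._acquire(g, "prelim" if self.write else "read")
        except GridCompetitionError:
            self.locker._release_all()
            raise
        return _LockRegion(self.locker, region)

    def __exit__(self, exc_type, exc, tb):
        self.locker._release_all()
        return False


# ---------------------------------------------------------------------------
# Shared mailboxes and the worker loop.

class SharedChannels:
    """Clock, instruction slots and per-worker result mailboxes."""

    def __init__(self, max_pid):
        self.max_pid = max_pid
        self.clock = sharedctypes.RawValue("q", 0)
        self.instructions = _shm.zeros((max_pid + 1, 2), "int64", True)
        self.results = _shm.zeros((max_pid + 1, RESULT_CAPACITY, 3),
                                  "int64", True)
        self.written = _shm.zeros(max_pid + 1, "int64", True)
        self.consumed = _shm.zeros(max_pid + 1, "int64", True)

    def post(self, pid, code, a=0, b=0):
        """Append one result record (worker side); blocks if the ring is
        full until the admin has consumed older records."""
        w = int(self.written[pid])
        while w - int(self.consumed[pid]) >= RESULT_CAPACITY:
            time.sleep(1e-4)
        self.results[pid, w % RESULT_CAPACITY] = (code, a, b)
        self.written[pid] = w + 1

    def drain(self, pid, read_count):
        """Records written by `pid` since `read_count` (admin side)."""
        w = int(self.written[pid])
        out = []
        for k in range(read_count, w):
            rec = self.results[pid, k % RESULT_CAPACITY]
            out.append((int(rec[0]), int(rec[1]), int(rec[2])))
        self.consumed[pid] = w
        return out, w


def _worker_recorder(channels, pid):
    def record(event):
        code = _EVENT_TO_CODE[event[0]]
        a = event[1] if len(event) > 1 else 0
        b = event[2] if len(event) > 2 else 0
        channels.post(pid, code, a, b)
    return record


def worker_loop(sim, pid, start_cycle=0):
    """Body of one processing core (runs in a forked process).

    Polls the clock; each cycle fetches front IDs from its two instruction
    slots (clearing a slot signals the admin that processing started), runs
    ``manage_front`` under a per-(seed, pid, cycle) random stream, streams
    results, and finishes the cycle on the sentinel ID, then sleep-polls
    with bounded exponential backoff until the next cycle.

    ``start_cycle`` is the clock value at fork time, passed by the admin so
    that a slowly starting worker cannot mistake an already-running cycle
    for one it has finished.
    """
    channels = sim._parallel_engine.channels
    tables = sim._parallel_engine.tables
    ins = channels.instructions
    store = sim.store
    my_cycle = start_cycle
    idle = 5e-5
    while True:
        c = int(channels.clock.value)
        if c == SHUTDOWN:
            return
        if c == my_cycle:
            time.sleep(idle)
            idle = min(idle * 2.0, 2e-3)
            continue
        idle = 5e-5
        my_cycle = c
        sim.cycle = c   # worker-local copy used by birth stamps
        rng = np.random.default_rng(
            np.random.SeedSequence((sim.seed, pid, my_cycle)))
        con = Constellation(sim, pid=pid, rng=rng, recorder=lambda e: None)
        con._record = _worker_recorder(channels, pid)
        con._locker = GridLocker(tables, sim.grid_config, pid,
                                 timeout=sim.lock_timeout,
                                 constellation=con)
        _run_worker_cycle(sim, pid, con, channels, tables, ins, store,
                          my_cycle)


def _run_worker_cycle(sim, pid, con, channels, tables, ins, store, cycle):
    pause = 5e-5
    while True:
        packed = 0
        for k in (0, 1):
            v = int(ins[pid, k])
            if v > 0:
                ins[pid, k] = 0
                packed = v
                break
        if packed == 0:
            for k in (0, 1):
                if int(ins[pid, k]) == SENTINEL:
                    ins[pid, k] = 0
                    channels.post(pid, R_GCE, con.gce_count)
                    channels.post(pid, R_CYCLE_DONE, cycle)
                    return
            time.sleep(pause)
            pause = min(pause * 1.5, 1e-3)
            continue
        pause = 5e-5
        fid = unpack_id(packed)
        front = store.get_front(fid)
        sched_gids = grid.front_to_gids(front.orig, front.end, front.radius,
                                        sim.grid_config)
        try:
            con._current = fid
            front.manage_front(con)
        except SimulationError:
            channels.post(pid, R_ERROR, packed, 1)
        except Exception:
            channels.post(pid, R_ERROR, packed, 2)
        finally:
            con._current = None
            con._locker._release_all()
            # release the scheduling locks the admin set for this front
            for g in sched_gids:
                if int(tables.write_lock[g]) == pid:
                    tables.write_lock[g] = 0
            channels.post(pid, R_DONE, packed)


# ---------------------------------------------------------------------------
# The admin side.

class ParallelEngine:
    """Forks the workers and runs the admin's side of each cycle:
    scheduling with preliminary write locks, broker pumping, result
    consumption and end-of-cycle serial work."""

    def __init__(self, sim):
        self.sim = sim
        self.num_workers = sim.num_workers
        self.max_pid = sim.num_workers + 1
        self.channels = SharedChannels(self.max_pid)
        self.tables = LockTables(sim.grid_config.n_gids, self.max_pid,
                                 shared=True)
        self._read_counts = [0] * (self.max_pid + 1)
        self.worker_errors = []
        self.audit_log = []   # per cycle: (scheduled packed ids, done ids)
        self._procs = []
        self._started = False

    def _start(self):
        if self._started:
            return
        start_cycle = int(self.channels.clock.value)
        for pid in range(2, self.max_pid + 1):
            p = Process(target=worker_loop,
                        args=(self.sim, pid, start_cycle),
                        daemon=True)
            p.start()
            self._procs.append(p)
        self._started = True

    def shutdown(self):
        if not self._started:
            return
        self.channels.clock.value = SHUTDOWN
        for p in self._procs:
            p.join(timeout=5.0)
        for p in self._procs:
            if p.is_alive():
                p.terminate()
                p.join(timeout=2.0)
        self._started = False

    # -- one simulation_loop call ------------------------------------------
    def run(self, n_cycles):
        sim = self.sim
        self._start()
        for _ in range(int(n_cycles)):
            sim.cycle += 1
            gce = self._run_cycle()
            sim._finish_cycle(gce)
        return sim

    def _run_cycle(self):
        sim = self.sim
        channels = self.channels
        tables = self.tables
        ins = channels.instructions
        growing, migrating, other = sim._schedule()
        backlog = [*growing, *migrating, *other]
        gid_cache = {}
        for fid in backlog:
            f = sim.store.get_front(fid)
            gid_cache[pack_id(fid)] = grid.front_to_gids(
                f.orig, f.end, f.radius, sim.grid_config)
        backlog = [pack_id(f) for f in backlog]
        scheduled_ids = list(backlog)
        self._done_list = []
        sentinel_sent = set()
        done_pids = set()
        inflight = {pid: 0 for pid in range(2, self.max_pid + 1)}
        self._inflight_counts = inflight
        self._inflight_map = {}
        gce_by_pid = {}
        channels.clock.value = sim.cycle

        last_progress = time.monotonic()
        hard_deadline = last_progress + max(60.0, 30.0 * sim.lock_timeout)
        while len(done_pids) < self.num_workers:
            progressed = False
            for _ in range(8):
                lock_broker_step(tables)
            progressed |= self._consume(done_pids, gce_by_pid)
            progressed |= self._schedule_pass(backlog, gid_cache, inflight,
                                              sentinel_sent, ins)
            for _ in range(8):
                lock_broker_step(tables)
            if progressed:
                last_progress = time.monotonic()
            else:
                now = time.monotonic()
                if (backlog and not any(inflight.values())
                        and now - last_progress > 2.0 * sim.lock_timeout):
                    # workers are idle yet fronts stay deferred: the locks
                    # blocking them can only be stale — clear and retry
                    self._clear_worker_locks()
                    last_progress = now
                elif now > hard_deadline:
                    self._check_workers()
                    raise RuntimeError(
                        "parallel cycle stalled: no progress before the "
                        "watchdog deadline")
                time.sleep(2e-5)
        # workers are quiescent: any leftover lock entries are stale
        self._clear_worker_locks()
        self._check_workers()
        self.audit_log.append((scheduled_ids, list(self._done_list)))
        return gce_by_pid

    def _consume(self, done_pids, gce_by_pid):
        sim = self.sim
        progressed = False
        for pid in range(2, self.max_pid + 1):
            recs, new_count = self.channels.drain(pid,
                                                  self._read_counts[pid])
            if not recs:
                continue
            progressed = True
            self._read_counts[pid] = new_count
            for code, a, b in recs:
                if code == R_DONE:
                    self._inflight_done(pid, a)
                elif code == R_CYCLE_DONE:
                    done_pids.add(pid)
                elif code == R_GCE:
                    gce_by_pid[pid] = gce_by_pid.get(pid, 0) + a
                elif code == R_ERROR:
                    self.worker_errors.append((sim.cycle, pid,
                                               unpack_id(a), b))
                else:
                    event = (_CODE_TO_EVENT[code], a, b) \
                        if code == R_FLAGS else (_CODE_TO_EVENT[code], a)
                    sim._events.append(event)
        return progressed

    def _inflight_done(self, pid, packed):
        self._done_list.append(packed)
        self._inflight_map.pop(packed, None)
        self._inflight_counts[pid] = max(0,
                                         self._inflight_counts[pid] - 1)

    def _schedule_pass(self, backlog, gid_cache, inflight, sentinel_sent,
                       ins):
        tables = self.tables
        progressed = False
        for pid in range(2, self.max_pid + 1):
            if pid in sentinel_sent:
                continue
            free = [k for k in (0, 1) if int(ins[pid, k]) == 0]
            if not free:
                continue
            if not backlog:
                # prefetch drained: end this worker's cycle
                ins[pid, free[0]] = SENTINEL
                sentinel_sent.add(pid)
                progressed = True
                continue
            # keep two IDs queued while the backlog is large, one near the
            # end so slow fronts are not hoarded by one core
            want = 2 if len(backlog) > 2 else 1
            queued = 2 - len(free)
            for k in free:
                if queued >= want or not backlog:
                    break
                chosen = None
                for i, packed in enumerate(backlog):
                    gids = gid_cache[packed]
                    if all(int(tables.write_lock[g]) in (0, pid)
                           for g in gids):
                        chosen = i
                        break
                if chosen is None:
                    break  # everything conflicts; retry next pass
                packed = backlog.pop(chosen)
                for g in gid_cache[packed]:
                    if int(tables.write_lock[g]) == 0:
                        tables.write_lock[g] = pid
                self._inflight_map[packed] = pid
                inflight[pid] += 1
                ins[pid, k] = packed
                queued += 1
                progressed = True
        return progressed

    def _clear_worker_locks(self):
        for arr in (self.tables.write_lock, self.tables.read_lock):
            nz = np.nonzero(arr)[0]
            for g in nz:
                arr[g] = 0

    def _check_workers(self):
        for pid, p in zip(range(2, self.max_pid + 1), self._procs):
            if not p.is_alive():
                raise RuntimeError(f"worker core {pid} died unexpectedly "
                                   f"(exit code {p.exitcode})")
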