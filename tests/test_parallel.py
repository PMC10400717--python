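"""The shared-memory parallel engine: lock-broker protocol, private-section
allocation, scheduling, and small end-to-end parallel runs."""

import numpy as np
import pytest

from frontsim import errors, models
from frontsim.fronts import Front, FrontStore
from frontsim.parallel import (LockTables, acquire_with_timeout,
                               lock_broker_step, release_lock)

from conftest import assert_no_illegal_overlaps


def tables(n_gids=20, max_pid=9):
    return LockTables(n_gids, max_pid)


class TestReadLockSequence:
    def test_contended_read_grants_serialize(self):
        """Two cores ask to read the same gid; a third reads elsewhere.
        The broker grants the free gids, the loser waits for the release."""
        t = tables()
        t.rreq[2] = 7
        t.rreq[3] = 7
        t.rreq[4] = 11
        lock_broker_step(t)
        assert t.read_lock[7] == 2 and t.read_lock[11] == 4
        assert t.rreq[2] == 0 and t.rreq[4] == 0
        assert t.rreq[3] == 7          # still pending
        # cores 2 and 4 finish reading and clear their locks
        t.read_lock[7] = 0
        t.read_lock[11] = 0
        lock_broker_step(t)
        assert t.read_lock[7] == 3 and t.rreq[3] == 0
        t.read_lock[7] = 0

    def test_read_denied_under_full_write_lock(self):
        t = tables()
        t.write_lock[5] = -3           # core 3 holds a full write lock
        t.rreq[2] = 5
        lock_broker_step(t)
        assert t.read_lock[5] == 0 and t.rreq[2] == 5
        t.write_lock[5] = 0
        lock_broker_step(t)
        assert t.read_lock[5] == 2

    def test_read_allowed_under_preliminary_write_lock(self):
        t = tables()
        t.write_lock[5] = 3            # preliminary (positive entry)
        t.rreq[2] = 5
        lock_broker_step(t)
        assert t.read_lock[5] == 2


class TestWriteLockSequence:
    def test_two_stage_write_with_waiting_competitor(self):
        """Preliminary then full write lock for one core while another's
        preliminary request waits, granted only after the release."""
        t = tables()
        t.wreq[2] = 8
        t.wreq[3] = 8
        lock_broker_step(t)
        assert t.write_lock[8] == 2 and t.wreq[2] == 0
        assert t.wreq[3] == 8
        # core 2 upgrades with the negated gid
        t.wreq[2] = -8
        lock_broker_step(t)
        assert t.write_lock[8] == -2
        assert t.wreq[3] == 8          # still pending under full lock
        # core 2 writes, then releases
        t.write_lock[8] = 0
        lock_broker_step(t)
        assert t.write_lock[8] == 3

    def test_full_upgrade_requires_preliminary_holder(self):
        t = tables()
        t.write_lock[4] = 2
        t.wreq[3] = -4                 # core 3 never held the preliminary
        lock_broker_step(t)
        assert t.write_lock[4] == 2 and t.wreq[3] == -4

    def test_full_upgrade_waits_for_readers(self):
        t = tables()
        t.write_lock[6] = 2
        t.read_lock[6] = 5
        t.wreq[2] = -6
        lock_broker_step(t)
        assert t.write_lock[6] == 2    # reader still on the gid
        t.read_lock[6] = 0
        lock_broker_step(t)
        assert t.write_lock[6] == -2

    def test_reentrant_grants_are_idempotent(self):
        t = tables()
        t.write_lock[9] = 2
        t.wreq[2] = 9                  # asks again for what it holds
        lock_broker_step(t)
        assert t.write_lock[9] == 2 and t.wreq[2] == 0
        t.read_lock[3] = 4
        t.rreq[4] = 3
        lock_broker_step(t)
        assert t.read_lock[3] == 4 and t.rreq[4] == 0


class TestAcquireWithTimeout:
    def test_uncontended_grant(self):
        t = tables()
        pump = lambda: lock_broker_step(t)  # noqa: E731
        assert acquire_with_timeout(t, 2, 5, "prelim", timeout=0.5,
                                    pump=pump)
        assert t.write_lock[5] == 2

    def test_timeout_raises_grid_competition(self):
        t = tables()
        t.write_lock[5] = 3            # held by someone else, never freed
        fake_now = [0.0]

        def clock():
            fake_now[0] += 0.01
            return fake_now[0]

        with pytest.raises(errors.GridCompetitionError):
            acquire_with_timeout(t, 2, 5, "prelim", timeout=1.0,
                                 pump=lambda: lock_broker_step(t),
                                 clock=clock, sleep=lambda s: None)
        assert t.wreq[2] == 0          # request withdrawn

    def test_grant_ledger_under_hammering(self):
        """8 cores hammer 10 gids; every grant is matched by a release and
        no two conflicting locks are ever co-held (logical clock)."""
        rng = np.random.default_rng(42)
        t = tables(n_gids=10, max_pid=9)
        held = {pid: None for pid in range(2, 10)}   # pid -> (gid, mode)
        hold_left = {pid: 0 for pid in range(2, 10)}
        grants = releases = 0
        ops = 0
        while ops < 1000:
            lock_broker_step(t)
            # audit: table-level conflict freedom
            for g in range(1, 11):
                w = int(t.write_lock[g])
                r = int(t.read_lock[g])
                if w < 0:
                    assert r in (0, -w), "reader co-held with full lock"
            for pid in range(2, 10):
                if held[pid] is not None:
                    gid, mode = held[pid]
                    granted = (int(t.read_lock[gid]) == pid
                               if mode == "read"
                               else int(t.write_lock[gid]) == pid)
                    if hold_left[pid] == 0 and granted:
                        release_lock(t, pid, gid,
                                     "read" if mode == "read" else "write")
                        releases += 1
                        held[pid] = None
                    elif granted:
                        hold_left[pid] -= 1
                    continue
                # idle: maybe post a new request
                if rng.random() < 0.6:
                    gid = int(rng.integers(1, 11))
                    mode = "read" if rng.random() < 0.5 else "prelim"
                    if mode == "read":
                        if t.rreq[pid] == 0:
                            t.rreq[pid] = gid
                    else:
                        if t.wreq[pid] == 0:
                            t.wreq[pid] = gid
                    held[pid] = (gid, mode)
                    hold_left[pid] = int(rng.integers(0, 3))
                    grants += 1
                    ops += 1
        # drain: let every pending request resolve, then release
        for _ in range(200):
            lock_broker_step(t)
            for pid in range(2, 10):
                if held[pid] is not None:
                    gid, mode = held[pid]
                    granted = (int(t.read_lock[gid]) == pid
                               if mode == "read"
                               else int(t.write_lock[gid]) == pid)
                    if granted:
                        release_lock(t, pid, gid,
                                     "read" if mode == "read" else "write")
                        releases += 1
                        held[pid] = None
        assert all(h is None for h in held.values())
        assert grants == releases == ops
        assert np.count_nonzero(t.read_lock) == 0
        assert np.count_nonzero(t.write_lock) == 0


class TestPrivateSectionAllocation:
    def test_worked_id_sequence_replay(self):
        """Three somata seeded by the admin, children allocated by three
        cores over two cycles, reproducing the worked index sequence with
        100-slot private sections."""

        class SubOne(Front):
            def manage_front(self, constellation):
                pass

        class SubTwo(Front):
            def manage_front(self, constellation):
                pass

        store = FrontStore([SubOne, SubTwo], capacity=400, num_sections=4)
        # initialisation: admin (core 1) makes the three somata
        assert store.allocate(1, 1) == 1      # (1,1)
        assert store.allocate(1, 1) == 2      # (1,2)
        assert store.allocate(1, 2) == 1      # (2,1)
        # cycle 1: each soma processed on its own core
        assert store.allocate(2, 1) == 101    # (1,101)
        assert store.allocate(2, 1) == 102    # (1,102)
        assert store.allocate(3, 1) == 201    # (1,201)
        assert store.allocate(3, 1) == 202    # (1,202)
        assert store.allocate(4, 2) == 301    # (2,301)
        # cycle 2: scheduling happens to hand fronts to other cores
        assert store.allocate(2, 1) == 103    # (1,103)
        assert store.allocate(3, 1) == 203    # (1,203)
        assert store.allocate(2, 1) == 104    # (1,104)
        assert store.allocate(2, 1) == 105    # (1,105)

    def test_subclass_rows_tracked_independently(self):
        class A(Front):
            def manage_front(self, constellation):
                pass

        class B(Front):
            def manage_front(self, constellation):
                pass

        store = FrontStore([A, B], capacity=100, num_sections=2)
        assert store.allocate(2, 1) == 51
        assert store.allocate(2, 2) == 51
        assert store.allocate(2, 1) == 52

    def test_overflow_on_101st_front(self):
        class A(Front):
            def manage_front(self, constellation):
                pass

        store = FrontStore([A], capacity=200, num_sections=2)
        for _ in range(100):
            store.allocate(2, 1)
        with pytest.raises(errors.OverflowError):
            store.allocate(2, 1)


@pytest.mark.timeout(300)
class TestParallelRuns:
    def test_small_parallel_run_is_consistent(self):
        sim = models.run_random_growth(seed=13, n_cycles=24, num_cores=3)
        try:
            eng = sim._parallel_engine
            assert not eng.worker_errors
            assert sim.store.live_count() > 20
            # exactly-once dispatch, every cycle
            for scheduled, done in eng.audit_log:
                assert sorted(scheduled) == sorted(done)
            # private-section discipline: creators own their indices
            for fid in sim.store.iter_ids():
                assert 1 <= fid.index <= sim.store.capacity
            assert_no_illegal_overlaps(sim.store)
        finally:
            sim.destruction()

    def test_four_worker_run_obeys_invariants(self):
        sim = models.run_random_growth(seed=21, n_cycles=24, num_cores=5)
        try:
            for scheduled, done in sim._parallel_engine.audit_log:
                assert sorted(scheduled) == sorted(done)
            assert_no_illegal_overlaps(sim.store)
            # path-length invariant over the final tree
            for fid in sim.store.iter_ids():
                f = sim.store.get_front(fid)
                if f.parent is None:
                    continue
                parent = sim.store.get_front(f.parent)
                assert f.path_length == pytest.approx(
                    parent.path_length + f.length(), abs=1e-6)
        finally:
            sim.destruction()

    def test_sentinel_only_cycles(self):
        """With no enabled fronts the workers see only sentinels."""
        from frontsim.engine import Simulator

        class Quiet(Front):
            def manage_front(self, constellation):
                self.disable(constellation)

        sim = Simulator([Quiet], volume=(100., 100., 100.), seed=0,
                        num_cores=3, capacity=600)
        try:
            sim.add_neurons(Quiet, "q", n=1, origins=[(50., 50., 50.)],
                            soma_radius=5.0)
            sim.simulation_loop(3)
            assert sim.cycle == 3
            logs = sim._parallel_engine.audit_log
            assert [len(s) for s, _ in logs] == [1, 0, 0]
        finally:
            sim.destruction()
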