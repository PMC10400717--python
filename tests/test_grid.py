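"""Grid index: allocation rule, linked blocks, neighbours, collision query
equivalence and occupancy stats."""

import numpy as np
import pytest

from frontsim import errors
from frontsim.fronts import FrontID, FrontStore, SHAPE_CYLINDER, \
    SHAPE_SPHERE, pack_id
from frontsim.geometry import segment_segment_distance
from frontsim.grid import (GridConfig, GridIndexMap, collision_query,
                           front_to_gids, grid_stats, neighbors)

from conftest import ScriptedFront


def cfg(step=20.0, size=200.0, block=10):
    return GridConfig((0, 0, 0), (size, size, size), grid_step=step,
                      block_size=block)


class TestFrontToGids:
    def test_small_front_at_lattice_point(self):
        c = cfg(step=20.0)
        gids = front_to_gids((40, 40, 40), (41, 40, 40), 0.5, c)
        assert len(gids) == 1

    def test_seven_um_front_gets_one_or_two_gids(self):
        c = cfg(step=10.0)
        counts = set()
        for x0 in np.linspace(31.0, 49.0, 40):
            gids = front_to_gids((x0, 40, 40), (x0 + 7.0, 40, 40), 1.0, c)
            counts.add(len(gids))
        assert counts <= {1, 2} and counts >= {1, 2}

    def test_long_front_gets_at_least_three_gids(self):
        c = cfg(step=10.0)
        gids = front_to_gids((40, 40, 40), (70, 40, 40), 1.0, c)
        assert len(gids) >= 3

    def test_outside_volume_raises(self):
        c = cfg()
        with pytest.raises(errors.VolumeError):
            front_to_gids((-1, 0, 0), (5, 0, 0), 1.0, c)

    def test_nearest_lattice_point_always_included(self):
        """Soundness core: for any point on the axis, its nearest lattice
        point is registered."""
        c = cfg(step=10.0, size=100.0)
        rng = np.random.default_rng(5)
        for _ in range(200):
            a = rng.uniform(10, 90, 3)
            b = a + rng.uniform(-8, 8, 3)
            b = np.clip(b, 0, 100)
            gids = set(front_to_gids(a, b, 1.0, c))
            for t in np.linspace(0, 1, 7):
                p = a + t * (b - a)
                ix = np.clip(np.round(p / 10.0).astype(int), 0,
                             np.array(c.dims) - 1)
                assert c.gid_from_ixyz(*ix) in gids

    def test_thick_front_warns(self):
        c = cfg(step=10.0)
        with pytest.warns(UserWarning, match="grid_step"):
            front_to_gids((40, 40, 40), (41, 40, 40), 8.0, c)


class TestNeighbors:
    def test_interior_has_26(self):
        c = cfg(step=20.0, size=200.0)
        g = c.gid_from_ixyz(5, 5, 5)
        assert len(neighbors(g, c)) == 26

    def test_corner_has_7(self):
        c = cfg()
        assert len(neighbors(c.gid_from_ixyz(0, 0, 0), c)) == 7

    def test_face_center_has_17(self):
        c = cfg()
        assert len(neighbors(c.gid_from_ixyz(0, 5, 5), c)) == 17


class TestRegisterDeregister:
    def test_block_overflow_links_new_block(self):
        c = cfg(block=10)
        m = GridIndexMap(c, num_sections=1)
        gid = 100
        for k in range(1, 11):
            m.register(gid, k)
        first = int(m.grid[gid])
        # 10 entries fit exactly into one block
        assert int(m.extra[first + 9]) == 10
        # the 11th converts the last slot into a link, moving entry 10
        m.register(gid, 11)
        assert int(m.extra[first + 9]) < 0
        nxt = -int(m.extra[first + 9])
        assert int(m.extra[nxt]) == 10 and int(m.extra[nxt + 1]) == 11
        assert sorted(m.entries_at(gid)) == list(range(1, 12))

    def test_deregister_backfills_with_last_entry(self):
        c = cfg()
        m = GridIndexMap(c, num_sections=1)
        for k in range(1, 6):
            m.register(7, k)
        m.register(7, 99)
        m.deregister(7, 2)
        entries = m.entries_at(7)
        assert entries[1] == 99 and len(entries) == 5

    def test_deregister_only_entry_frees_gid(self):
        c = cfg()
        m = GridIndexMap(c, num_sections=1)
        m.register(5, 42)
        m.deregister(5, 42)
        assert int(m.grid[5]) == 0
        assert m.entries_at(5) == []

    def test_duplicate_registration_rejected(self):
        c = cfg()
        m = GridIndexMap(c, num_sections=1)
        m.register(5, 42)
        with pytest.raises(errors.UsageError):
            m.register(5, 42)

    def test_random_replay_returns_to_empty(self):
        c = cfg()
        m = GridIndexMap(c, num_sections=1)
        rng = np.random.default_rng(0)
        live = []
        for k in range(1, 1001):
            gid = int(rng.integers(1, c.n_gids + 1))
            m.register(gid, k)
            live.append((gid, k))
        rng.shuffle(live)
        for gid, k in live:
            m.deregister(gid, k)
        assert np.count_nonzero(m.grid) == 0
        assert np.count_nonzero(m.extra) == 0

    def test_round_trip_restores_structure_exactly(self):
        c = cfg()
        m = GridIndexMap(c, num_sections=1)
        for k in range(1, 12):
            m.register(9, k)
        snap_grid = m.grid.copy()
        snap_extra = m.extra.copy()
        m.register(9, 99)
        m.deregister(9, 99)
        assert np.array_equal(m.grid, snap_grid)
        assert np.array_equal(m.extra, snap_extra)

    def test_grid_extra_overflow(self):
        c = cfg()
        m = GridIndexMap(c, extra_capacity=30, num_sections=1)
        with pytest.raises(errors.OverflowError):
            for gid in range(1, 20):
                m.register(gid, gid)


def _random_scene(n_fronts, rng, size=100.0, rmax=2.0):
    """Random capsules (mix of spheres and cylinders) inside the box."""
    fronts = []
    for _ in range(n_fronts):
        a = rng.uniform(5, size - 5, 3)
        if rng.random() < 0.2:
            b = a.copy()
        else:
            b = np.clip(a + rng.uniform(-8, 8, 3), 0, size)
        fronts.append((a, b, rng.uniform(0.5, rmax)))
    return fronts


class TestCollisionQuery:
    def _build(self, fronts, step):
        c = GridConfig((0, 0, 0), (100.0, 100.0, 100.0), grid_step=step)
        store = FrontStore([ScriptedFront], capacity=len(fronts) + 1)
        m = GridIndexMap(c, num_sections=1,
                         extra_capacity=max(2000, 60 * len(fronts)))
        for k, (a, b, r) in enumerate(fronts, start=1):
            fid = FrontID(1, store.allocate(1, 1))
            shape = SHAPE_SPHERE if np.allclose(a, b) else SHAPE_CYLINDER
            store.init_front(fid, shape, a, b, r)
            for g in front_to_gids(a, b, r, c):
                m.register(g, pack_id(fid))
        return c, store, m

    def test_empty_scene_has_no_collision(self):
        c, store, m = self._build([], 20.0)
        assert collision_query(store, m, (50, 50, 50), (55, 50, 50),
                               1.0) is None

    def test_touching_is_not_collision(self):
        fronts = [((50, 50, 50), (60, 50, 50), 1.0)]
        c, store, m = self._build(fronts, 20.0)
        # parallel cylinders at axis distance exactly 2.0: touching
        assert collision_query(store, m, (50, 52, 50), (60, 52, 50),
                               1.0) is None
        # at 1.99: strict overlap
        assert collision_query(store, m, (50, 51.99, 50), (60, 51.99, 50),
                               1.0) is not None

    @pytest.mark.parametrize("step", [5.0, 10.0, 20.0])
    def test_matches_brute_force(self, step):
        rng = np.random.default_rng(int(step))
        fronts = _random_scene(150, rng)
        c, store, m = self._build(fronts, step)
        for _ in range(40):
            a = rng.uniform(5, 95, 3)
            b = np.clip(a + rng.uniform(-8, 8, 3), 0, 100)
            r = rng.uniform(0.5, 2.0)
            got = collision_query(store, m, a, b, r, mode="all")
            brute = [
                pack_id(FrontID(1, k))
                for k, (fa, fb, fr) in enumerate(fronts, start=1)
                if segment_segment_distance(a, b, fa, fb) < r + fr
            ]
            assert sorted(got) == sorted(brute)

    def test_first_mode_returns_lowest_scan_order_hit(self):
        fronts = [((50, 50, 50), (55, 50, 50), 1.0),
                  ((52, 50, 50), (57, 50, 50), 1.0)]
        c, store, m = self._build(fronts, 20.0)
        hit = collision_query(store, m, (51, 50.5, 50), (56, 50.5, 50), 1.0,
                              mode="first")
        all_hits = collision_query(store, m, (51, 50.5, 50),
                                   (56, 50.5, 50), 1.0, mode="all")
        assert hit == all_hits[0] and len(all_hits) == 2


class TestGridStats:
    def test_single_soma(self):
        c = cfg()
        store = FrontStore([ScriptedFront], capacity=10)
        m = GridIndexMap(c, num_sections=1)
        fid = FrontID(1, store.allocate(1, 1))
        store.init_front(fid, SHAPE_SPHERE, (40, 40, 40), None, 5.0)
        for g in front_to_gids((40, 40, 40), (40, 40, 40), 5.0, c):
            m.register(g, pack_id(fid))
        s = grid_stats(m, live_fronts=1)
        assert s["mean_gids_per_front"] == 1.0
        assert s["max_fronts_per_gid"] == 1

    def test_k_fronts_on_one_gid(self):
        c = cfg()
        m = GridIndexMap(c, num_sections=1)
        for k in range(1, 8):
            m.register(33, k)
        s = grid_stats(m, live_fronts=7)
        assert s["occupancy"] == pytest.approx(1.0 / c.n_gids)
        assert s["max_fronts_per_gid"] == 7
        assert s["frac_occupied_1_10"] == 1.0
        assert s["frac_occupied_1_5"] == 0.0

    def test_stats_match_direct_recount(self):
        c = cfg(step=10.0, size=100.0)
        rng = np.random.default_rng(3)
        m = GridIndexMap(c, num_sections=1, extra_capacity=40_000)
        regs = {}
        for k in range(1, 301):
            gids = rng.choice(np.arange(1, c.n_gids + 1),
                              size=rng.integers(1, 4), replace=False)
            for g in gids:
                m.register(int(g), k)
            regs[k] = set(int(g) for g in gids)
        s = grid_stats(m, live_fronts=300)
        total = sum(len(v) for v in regs.values())
        occupied = set.union(*regs.values())
        assert s["mean_gids_per_front"] == pytest.approx(total / 300)
        assert s["occupancy"] == pytest.approx(len(occupied) / c.n_gids)
        counts = {}
        for v in regs.values():
            for g in v:
                counts[g] = counts.get(g, 0) + 1
        assert s["max_fronts_per_gid"] == max(counts.values())
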