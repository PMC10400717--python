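"""The serial engine: seeding, growth, migration, retraction ordering,
collision recovery, determinism and resume."""

import hashlib

import numpy as np
import pytest

from frontsim import errors, models
from frontsim.engine import Simulator
from frontsim.fronts import FLAG_AXON_FRONT

from conftest import ScriptedFront, chain, grow_soma


class TestAddNeurons:
    def test_single_explicit_soma(self, small_sim):
        soma = grow_soma(small_sim, pos=(50, 50, 50), radius=10.0)
        assert soma.is_sphere() and soma.order == 0
        assert soma.path_length == 0.0

    def test_two_distant_somata(self, small_sim):
        cls = small_sim.store.front_classes[0]
        out = small_sim.add_neurons(cls, "pair", n=2,
                                    origins=[(20, 50, 50), (80, 50, 50)],
                                    soma_radius=10.0)
        assert len(out) == 2

    def test_overlapping_somata_raise_collision(self, small_sim):
        cls = small_sim.store.front_classes[0]
        small_sim.add_neurons(cls, "a", n=1, origins=[(40, 50, 50)],
                              soma_radius=10.0)
        with pytest.raises(errors.CollisionError):
            small_sim.add_neurons(cls, "b", n=1, origins=[(55, 50, 50)],
                                  soma_radius=10.0)

    def test_random_placement_respects_box_and_seed(self):
        for _ in range(2):
            sim = Simulator([ScriptedFront], volume=(100., 100., 100.),
                            seed=5, capacity=2000)
            sim.add_neurons(ScriptedFront, "r", n=3,
                            placement=((20, 20, 20), (80, 80, 80)),
                            soma_radius=5.0)
            pos = sorted(tuple(sim.store.get_front(f).orig)
                         for f in sim.store.iter_ids())
            sim.destruction()
            if _ == 0:
                first = pos
        assert pos == first
        for p in pos:
            assert all(20 <= v <= 80 for v in p)

    def test_soma_outside_volume(self, small_sim):
        cls = small_sim.store.front_classes[0]
        with pytest.raises(errors.VolumeError):
            small_sim.add_neurons(cls, "x", n=1, origins=[(120, 50, 50)],
                                  soma_radius=5.0)


class TestAddChild:
    def test_root_length_matches_offsets(self, small_sim):
        soma = grow_soma(small_sim, radius=10.0)
        child = small_sim.constellation.add_child(
            soma, soma.orig + (15.0, 0, 0), radius=2.0)
        assert child.length() == pytest.approx(5.0)
        assert child.path_length == pytest.approx(5.0)

    def test_default_radius_inherits_parent(self, small_sim):
        soma = grow_soma(small_sim)
        (root,) = chain(small_sim, soma, (1, 0, 0), 5.0, 1, radius=2.0)
        child = small_sim.constellation.add_child(root,
                                                  root.end + (5.0, 0, 0))
        assert child.radius == root.radius

    def test_volume_error_is_atomic(self, small_sim):
        soma = grow_soma(small_sim, pos=(95, 50, 50), radius=4.0)
        before = small_sim.store.created_count()
        with pytest.raises(errors.VolumeError):
            small_sim.constellation.add_child(soma, (103.0, 50.0, 50.0),
                                              radius=1.0)
        assert small_sim.store.created_count() == before
        assert soma.num_children == 0

    def test_collision_carries_offending_front(self, small_sim):
        cls = small_sim.store.front_classes[0]
        soma = grow_soma(small_sim, pos=(40, 50, 50), radius=5.0)
        (obstacle,) = small_sim.add_neurons(cls, "obs", n=1,
                                            origins=[(60, 50, 50)],
                                            soma_radius=5.0)
        with pytest.raises(errors.CollisionError) as exc:
            small_sim.constellation.add_child(soma, (57.0, 50.0, 50.0),
                                              radius=2.0)
        assert exc.value.collider == obstacle.id

    def test_collision_is_atomic(self, small_sim):
        cls = small_sim.store.front_classes[0]
        soma = grow_soma(small_sim, pos=(40, 50, 50), radius=5.0)
        small_sim.add_neurons(cls, "obs", n=1, origins=[(60, 50, 50)],
                              soma_radius=5.0)
        stats_before = small_sim.stats()
        created = small_sim.store.created_count()
        with pytest.raises(errors.CollisionError):
            small_sim.constellation.add_child(soma, (57.0, 50.0, 50.0),
                                              radius=2.0)
        assert small_sim.store.created_count() == created
        assert small_sim.stats() == stats_before


class TestMigration:
    def _soma(self, sim):
        soma = grow_soma(sim, pos=(50, 50, 50), radius=5.0)
        sim.constellation.enable(soma, growing=False, migrating=True)
        return soma

    def test_free_soma_moves(self, small_sim):
        soma = self._soma(small_sim)
        small_sim.constellation.migrate_soma(soma, (55.0, 50.0, 50.0))
        assert np.allclose(soma.orig, (55, 50, 50))

    def test_trailing_axon_extends_on_migration(self, small_sim):
        soma = self._soma(small_sim)
        con = small_sim.constellation
        con.add_child(soma, (43.0, 50.0, 50.0), radius=1.0, role="axon")
        n0 = small_sim.store.live_count()
        con.migrate_soma(soma, (57.0, 50.0, 50.0))
        assert small_sim.store.live_count() == n0 + 1
        axon_fronts = [small_sim.store.get_front(f)
                       for f in small_sim.store.iter_ids()
                       if small_sim.store.get_front(f).has_flag(
                           FLAG_AXON_FRONT)]
        assert len(axon_fronts) == 2
        (tip,) = [f for f in axon_fronts if f.is_terminal()]
        # the new segment ends on the new soma surface
        assert np.linalg.norm(tip.end - soma.orig) == pytest.approx(
            soma.radius)

    def test_filipodium_reanchors(self, small_sim):
        soma = self._soma(small_sim)
        con = small_sim.constellation
        fili = con.add_child(soma, (62.0, 50.0, 50.0), radius=0.5,
                             role="filipodium")
        tip_before = fili.end.copy()
        con.migrate_soma(soma, (54.0, 50.0, 50.0))
        assert np.allclose(fili.end, tip_before)
        assert np.linalg.norm(fili.orig - soma.orig) == pytest.approx(
            soma.radius)

    def test_soma_with_dendrites_cannot_migrate(self, small_sim):
        soma = self._soma(small_sim)
        chain(small_sim, soma, (0, 1, 0), 5.0, 1, radius=2.0)
        with pytest.raises(errors.UsageError):
            small_sim.constellation.migrate_soma(soma, (55.0, 50.0, 50.0))

    def test_blocked_migration_leaves_soma_unchanged(self, small_sim):
        soma = self._soma(small_sim)
        cls = small_sim.store.front_classes[0]
        small_sim.add_neurons(cls, "obs", n=1, origins=[(62, 50, 50)],
                              soma_radius=5.0)
        with pytest.raises(errors.CollisionError):
            small_sim.constellation.migrate_soma(soma, (54.0, 50.0, 50.0))
        assert np.allclose(soma.orig, (50, 50, 50))


class TestCycleOrdering:
    def test_retraction_and_growth_visible_next_cycle(self):
        log = []

        class Phased(ScriptedFront):
            def manage_front(self, constellation):
                cyc = constellation.cycle
                if self.is_sphere() and cyc == 1:
                    for k in range(2):
                        self.add_child(constellation,
                                       self.orig + np.array(
                                           [15.0 * (1 - 2 * k), 0, 15.0]),
                                       radius=2.0)
                elif self.is_cylinder() and cyc == 2:
                    if self.end[0] > 50:
                        self.retract(constellation)
                    else:
                        self.add_child(constellation,
                                       self.end + (0, 0, 5.0))
                    self.disable(constellation)
                else:
                    log.append(("seen", cyc, self.id))

        sim = Simulator([Phased], volume=(100., 100., 100.), seed=0,
                        capacity=500)
        try:
            sim.add_neurons(Phased, "p", n=1, origins=[(50, 50, 40)],
                            soma_radius=10.0)
            sim.simulation_loop(1)
            assert sim.front_count_log == [3]
            sim.simulation_loop(1)
            # one retraction and one growth applied at end of cycle 2
            assert sim.front_count_log == [3, 3]
        finally:
            sim.destruction()

    def test_zero_enabled_fronts_still_advances_clock(self):
        sim = Simulator([ScriptedFront], volume=(50., 50., 50.), seed=0,
                        capacity=100)
        try:
            sim.simulation_loop(10)
            assert sim.cycle == 10
            assert sim.store.created_count() == 0
        finally:
            sim.destruction()


class TestSolveCollision:
    def test_deflects_around_thin_obstacle(self, small_sim):
        cls = small_sim.store.front_classes[0]
        soma = grow_soma(small_sim, pos=(40, 50, 50), radius=5.0)
        (root,) = chain(small_sim, soma, (1, 0, 0), 5.0, 1, radius=1.0)
        small_sim.add_neurons(cls, "obs", n=1, origins=[(56, 50, 50)],
                              soma_radius=3.0)
        con = small_sim.constellation
        target = root.end + (5.0, 0.0, 0.0)
        with pytest.raises(errors.CollisionError) as exc:
            con.add_child(root, target)
        alt = con.solve_collision(root, target, exc.value)
        assert alt is not None
        child = con.add_child(root, alt)
        assert child.length() == pytest.approx(5.0, abs=1e-6)

    def test_enclosed_tip_fails(self, small_sim):
        cls = small_sim.store.front_classes[0]
        soma = grow_soma(small_sim, pos=(50, 50, 50), radius=5.0)
        (root,) = chain(small_sim, soma, (1, 0, 0), 4.0, 1, radius=1.0)
        # cage of obstacles enclosing every forward candidate direction
        anchor = root.end
        offsets = [(7, 0, 0), (0, 7, 0), (0, -7, 0), (0, 0, 7), (0, 0, -7)]
        for k, off in enumerate(offsets):
            small_sim.add_neurons(cls, f"o{k}", n=1,
                                  origins=[anchor + np.array(off, float)],
                                  soma_radius=4.5)
        con = small_sim.constellation
        target = root.end + (5.0, 0.0, 0.0)
        with pytest.raises(errors.CollisionError) as exc:
            con.add_child(root, target)
        assert con.solve_collision(root, target, exc.value) is None


class TestDeterminismAndResume:
    def test_serial_runs_are_byte_identical(self, tmp_path):
        digests = []
        for run in (1, 2):
            db = tmp_path / f"run{run}.db"
            swc = tmp_path / f"run{run}.swc"
            sim = models.run_random_growth(seed=11, n_cycles=12,
                                           db_path=str(db))
            sim.export_swc("rand_neuron", str(swc))
            sim.destruction()
            digests.append((hashlib.sha256(db.read_bytes()).hexdigest(),
                            hashlib.sha256(swc.read_bytes()).hexdigest()))
        assert digests[0] == digests[1]

    def test_import_round_trip_preserves_state(self, tmp_path):
        db = tmp_path / "trace.db"
        sim = models.run_random_growth(seed=4, n_cycles=8,
                                       db_path=str(db))
        want = [(f, tuple(sim.store.get_front(f).end),
                 sim.store.get_front(f).path_length,
                 sim.store.get_front(f).flags)
                for f in sim.store.iter_ids()]
        sim.destruction()

        p = models.RandomGrowthParams()

        class _R(models.RandomFront):
            params = p
        _R.__name__ = "RandomFront"
        sim2 = Simulator([_R], volume=p.volume, seed=4)
        try:
            sim2.import_simulation(str(db))
            got = [(f, tuple(sim2.store.get_front(f).end),
                    sim2.store.get_front(f).path_length,
                    sim2.store.get_front(f).flags)
                   for f in sim2.store.iter_ids()]
            assert got == want
            assert sim2.cycle == 8
        finally:
            sim2.destruction()

    def test_import_mismatched_registry_rejected(self, tmp_path):
        db = tmp_path / "trace.db"
        sim = models.run_random_growth(seed=4, n_cycles=2,
                                       db_path=str(db))
        sim.destruction()
        sim2 = Simulator([ScriptedFront], volume=(200., 200., 200.),
                         seed=4)
        try:
            with pytest.raises(errors.UsageError):
                sim2.import_simulation(str(db))
        finally:
            sim2.destruction()

    def test_resumed_run_continues_growing(self, tmp_path):
        db = tmp_path / "trace.db"
        sim = models.run_random_growth(seed=6, n_cycles=5,
                                       db_path=str(db))
        n5 = sim.store.live_count()
        sim.destruction()
        p = models.RandomGrowthParams()

        class _R(models.RandomFront):
            params = p
        _R.__name__ = "RandomFront"
        sim2 = Simulator([_R], volume=p.volume, seed=6)
        try:
            sim2.import_simulation(str(db))
            sim2.simulation_loop(5)
            assert sim2.cycle == 10
            assert sim2.store.live_count() > n5
        finally:
            sim2.destruction()


class TestNoOverlapInvariant:
    def test_completed_run_has_no_nonadjacent_overlap(self):
        from conftest import assert_no_illegal_overlaps
        sim = models.run_random_growth(seed=2, n_cycles=25)
        try:
            assert_no_illegal_overlaps(sim.store)
        finally:
            sim.destruction()
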