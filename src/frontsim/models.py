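"""Fixture models: stochastic random growth, soma migration along a
substrate gradient, and synapse-count-based dendrite pruning.

These are complete, runnable growth scripts written the way user models are:
a ``Front`` subclass whose ``manage_front`` encodes the rule, plus a driver
function that seeds the volume and runs the loop.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import geometry
from .engine import Simulator
from .errors import (CollisionError, GridCompetitionError, InsideParentError,
                     SamplingError, VolumeError)
from .fronts import Front

_GROWTH_ERRORS = (CollisionError, InsideParentError, VolumeError,
                  GridCompetitionError)

# event tags stored in the per-front `kind` attribute
KIND_ROOT = 1.0
KIND_EXTENSION = 2.0
KIND_BRANCH = 3.0


@dataclass
class RandomGrowthParams:
    """Parameters of the stochastic random-growth example model.

    The soma sprouts dendritic roots from candidate directions; each
    dendrite front then either extends (one child within a narrow cone) or
    branches (two tapered children), until its accumulated path length
    reaches the termination bound.
    """

    soma_radius: float = 10.0       # um
    root_radius: float = 2.0        # um; dendrites are thinner than the soma
    n_roots: int = 5                # roots grown before the soma is disabled
    n_candidates: int = 10          # candidate directions drawn at the soma
    root_length: float = 15.0       # um, offset of a root end from the soma
                                    # centre (the root starts on the surface)
    extension_prob: float = 0.94
    branch_prob: float = 0.06
    cone_angle: float = 20.0        # degrees around the current heading
    step_length: float = 5.0        # um per extension/branch child
    max_path_length: float = 100.0  # um; growth terminates at/after this
    taper_factor: float = 0.9       # radius shrink at branch points
    n_branch_candidates: int = 4    # fewer random points than at the soma
    extension_retry_cap: int = 100
    volume: tuple = ((0.0, 0.0, 0.0), (200.0, 200.0, 200.0))

    def __post_init__(self):
        if abs(self.extension_prob + self.branch_prob - 1.0) > 1e-12:
            raise ValueError("extension_prob + branch_prob must equal 1")


class RandomFront(Front):
    """Random growth rule: 5 roots, then 94% extension / 6% branching per
    front per cycle, terminating at a 100 um path length."""

    attributes = ("kind",)
    params = RandomGrowthParams()

    def manage_front(self, constellation):
        p = self.params
        rng = constellation.rng
        if self.order == 0:
            # the soma: grow dendrite roots by trial and error
            points = self.unit_branching_sample(constellation,
                                                p.n_candidates)
            num_dend = 0
            for direction in points:
                new_pos = self.orig + direction * p.root_length
                try:
                    child = self.add_child(constellation, new_pos,
                                           radius=p.root_radius)
                except _GROWTH_ERRORS:
                    continue
                child.kind = KIND_ROOT
                num_dend += 1
                if num_dend == p.n_roots:
                    break
            self.disable(constellation)
        elif self.path_length < p.max_path_length:
            if rng.random() < p.extension_prob:
                self._extend(constellation, p)
            else:
                self._branch(constellation, p)
        else:
            # growth termination
            self.disable(constellation)

    def _extend(self, constellation, p):
        gce = 0
        for _ in range(p.extension_retry_cap):
            direction = self.unit_heading_sample(constellation, p.cone_angle)
            new_pos = self.end + direction * p.step_length
            try:
                child = self.add_child(constellation, new_pos)
            except GridCompetitionError:
                # another core is growing here right now: a new random
                # direction will not help, so give up for this cycle and
                # stay enabled to try again on the next one
                gce += 1
                if gce >= 3:
                    return
                continue
            except _GROWTH_ERRORS:
                continue
            child.kind = KIND_EXTENSION
            break
        self.disable(constellation)

    def _branch(self, constellation, p):
        try:
            points = self.unit_branching_sample(constellation,
                                                p.n_branch_candidates)
        except SamplingError:
            points = []
        radius = self.taper(p.taper_factor)
        made = 0
        gce = 0
        for direction in points:
            new_pos = self.end + direction * p.step_length
            try:
                child = self.add_child(constellation, new_pos, radius=radius)
            except GridCompetitionError:
                gce += 1
                if made == 0 and gce >= 2:
                    return  # postpone the whole branch event to next cycle
                continue
            except _GROWTH_ERRORS:
                continue
            child.kind = KIND_BRANCH
            made += 1
            if made == 2:
                break
        self.disable(constellation)


def run_random_growth(seed=0, n_cycles=30, num_cores=2, db_path=None,
                      params=None, n_neurons=1, **sim_kwargs):
    """Seed and run the random-growth model; returns the Simulator.

    The caller owns the simulator (use it as a context manager or call
    ``destruction``).
    """
    p = params or RandomGrowthParams()
    # dense same-neuron growth makes grid competition common in parallel
    # runs; a short lock timeout turns waiting into cheap retries
    sim_kwargs.setdefault("lock_timeout", 0.05)

    class _Rand(RandomFront):
        params = p
    _Rand.__name__ = "RandomFront"

    sim = Simulator([_Rand], volume=p.volume, num_cores=num_cores,
                    seed=seed, db_path=db_path, **sim_kwargs)
    centre = (np.asarray(p.volume[0]) + np.asarray(p.volume[1])) / 2.0
    sim.add_neurons(_Rand, "rand_neuron", n=n_neurons,
                    origins=[centre] if n_neurons == 1 else None,
                    placement=(None if n_neurons == 1 else
                               (np.asarray(p.volume[0]) + 40,
                                np.asarray(p.volume[1]) - 40)),
                    soma_radius=p.soma_radius)
    sim.simulation_loop(n_cycles)
    return sim


# ---------------------------------------------------------------------------
# Migration demo: filipodium-led chemotactic soma migration with a trailing
# axon, as in the classic five-somata-to-a-substrate-line scene.

@dataclass
class MigrationParams:
    soma_radius: float = 5.0
    fili_radius: float = 0.6
    fili_length: float = 10.0       # um, exploratory reach of the filipodium
    axon_radius: float = 0.8
    soma_step: float = 4.0          # um migrated per cycle
    n_probe: int = 7                # candidate directions probed per cycle
    probe_cone: float = 60.0        # degrees around the current tip heading
    stop_concentration: float = 1500.0  # molecule count at which the
                                        # filipodium retracts and migration
                                        # stops (reached close to a source)
    n_dendrites: int = 3
    dendrite_length: float = 8.0
    dendrite_radius: float = 1.0
    stochastic_sensing: bool = True
    volume: tuple = ((0.0, 0.0, 0.0), (120.0, 120.0, 120.0))

    # phases stored in the soma's `phase` attribute
    PHASE_MIGRATE: float = 0.0
    PHASE_DENDRITES: float = 1.0
    PHASE_DONE: float = 2.0


class MigrationFront(Front):
    """Somata that follow their filipodium up a substrate gradient, leave a
    trailing axon, then grow dendrites once the cue saturates."""

    attributes = ("phase",)
    params = MigrationParams()

    def manage_front(self, constellation):
        p = self.params
        if self.is_sphere():
            if self.phase == p.PHASE_MIGRATE:
                self._migrate_step(constellation, p)
            elif self.phase == p.PHASE_DENDRITES:
                self._grow_dendrites(constellation, p)
            return
        if self.has_flag(16):  # FLAG_FILIPODIUM
            self._steer_filipodium(constellation, p)

    # -- soma ---------------------------------------------------------------
    def _migrate_step(self, constellation, p):
        store = constellation.store
        fili = self._filipodium(constellation)
        if fili is None:
            # bootstrap: probe directions, sprout filipodium + axon root
            direction = self._best_direction(
                constellation, geometry.random_unit_vector(
                    constellation.rng, n=p.n_probe), p)
            try:
                self.add_child(constellation,
                               self.orig + direction * (p.soma_radius
                                                        + p.fili_length),
                               radius=p.fili_radius, role="filipodium")
                self.add_child(constellation,
                               self.orig - direction * (p.soma_radius + 2.0),
                               radius=p.axon_radius, role="axon")
            except _GROWTH_ERRORS:
                pass
            return
        level = constellation.sample_concentration(
            fili.end, stochastic=p.stochastic_sensing)
        if level >= p.stop_concentration:
            # cue saturated: retract the filipodium, switch to dendrites
            self.retract_branch(constellation, fili)
            self.phase = p.PHASE_DENDRITES
            self.enable(constellation, growing=True)
            return
        target = fili.end
        d = target - self.orig
        dist = float(np.linalg.norm(d))
        if dist < 1e-9:
            return
        step = min(p.soma_step, max(dist - p.soma_radius, 0.0))
        if step <= 1e-9:
            return
        try:
            self.migrate_soma(constellation,
                              self.orig + d / dist * step)
        except (CollisionError, VolumeError, GridCompetitionError):
            pass

    def _grow_dendrites(self, constellation, p):
        try:
            points = self.unit_branching_sample(constellation,
                                                2 * p.n_dendrites)
        except SamplingError:
            points = []
        made = 0
        for direction in points:
            pos = self.orig + direction * (p.soma_radius + p.dendrite_length)
            try:
                self.add_child(constellation, pos, radius=p.dendrite_radius)
            except _GROWTH_ERRORS:
                continue
            made += 1
            if made == p.n_dendrites:
                break
        self.phase = p.PHASE_DONE
        self.disable(constellation)

    def _filipodium(self, constellation):
        for c in self.children():
            if c.has_flag(16) and not c.is_retracted():
                return c
        return None

    def _best_direction(self, constellation, candidates, p):
        best, best_level = None, -1.0
        for direction in candidates:
            probe = self.orig + direction * (p.soma_radius + p.fili_length)
            vmin, vmax = constellation.volume
            if np.any(probe < vmin) or np.any(probe > vmax):
                continue
            level = constellation.sample_concentration(
                probe, stochastic=p.stochastic_sensing)
            if level > best_level:
                best, best_level = direction, level
        if best is None:
            best = candidates[0]
        return best

    # -- filipodium ---------------------------------------------------------
    def _steer_filipodium(self, constellation, p):
        heading = self.heading()
        candidates = [heading] + list(geometry.unit_heading_sample(
            heading, p.probe_cone, constellation.rng, n=p.n_probe - 1))
        soma = constellation.store.get_front(self.soma_id)
        best, best_level = None, -1.0
        for direction in candidates:
            tip = soma.orig + direction * (soma.radius + p.fili_length)
            vmin, vmax = constellation.volume
            if np.any(tip < vmin) or np.any(tip > vmax):
                continue
            level = constellation.sample_concentration(
                tip, stochastic=p.stochastic_sensing)
            if level > best_level:
                best, best_level = direction, level
        if best is None:
            return
        tip = soma.orig + best * (soma.radius + p.fili_length)
        try:
            constellation.relocate_end(self, tip)
        except (CollisionError, VolumeError, GridCompetitionError):
            pass


class ObstacleFront(Front):
    """Inert somata that only repel others (they never grow)."""

    def manage_front(self, constellation):
        self.disable(constellation)


def migration_demo(seed=0, n_cycles=25, params=None, num_cores=2,
                   db_path=None, n_somata=1, substrate_positions=None,
                   obstacle_positions=(), substrate_n_mol=1e8,
                   substrate_diffusion=25.0, **sim_kwargs):
    """Filipodium-led migration toward substrate, with optional obstacles.

    Returns the Simulator (caller closes it).  With no substrate the somata
    perform an unbiased random walk; with a source the filipodia climb the
    sampled concentration and the somata follow, leaving trailing axons.
    """
    p = params or MigrationParams()
    sim_kwargs.setdefault("lock_timeout", 0.05)

    class _Mig(MigrationFront):
        params = p
    _Mig.__name__ = "MigrationFront"

    sim = Simulator([_Mig, ObstacleFront], volume=p.volume,
                    num_cores=num_cores, seed=seed, db_path=db_path,
                    substrate_names=("attractant",), **sim_kwargs)
    lo = np.asarray(p.volume[0])
    hi = np.asarray(p.volume[1])
    if substrate_positions is None:
        substrate_positions = [hi - np.array([20.0, 20.0 + 8.0 * k, 60.0])
                               for k in range(5)]
    if len(substrate_positions):
        sim.deposit_substrate("attractant", substrate_positions,
                              substrate_n_mol, substrate_diffusion)
    start = lo + (hi - lo) * np.array([0.45, 0.5, 0.5])
    origins = [start + np.array([0.0, 14.0 * k, 0.0])
               for k in range(n_somata)]
    somata = sim.add_neurons(_Mig, "migrating", n=n_somata, origins=origins,
                             soma_radius=p.soma_radius)
    for s in somata:
        sim.constellation.enable(s, growing=False, migrating=True)
    if len(obstacle_positions):
        sim.add_neurons(ObstacleFront, "obstacle", n=len(obstacle_positions),
                        origins=list(obstacle_positions), soma_radius=4.0)
    sim.simulation_loop(n_cycles)
    return sim


# ---------------------------------------------------------------------------
# Retraction demo: dendrites with too few synapses are pruned in one cycle.

@dataclass
class RetractionParams:
    soma_radius: float = 5.0
    n_dendrites: int = 8
    fronts_per_dendrite: int = 3
    segment_length: float = 8.0
    dendrite_radius: float = 1.0
    synapse_threshold: int = 5      # dendrites with fewer synapses retract
    synapse_counts: tuple = (0, 1, 2, 3, 4, 5, 6, 9)
    bouton_radius: float = 0.4
    volume: tuple = ((0.0, 0.0, 0.0), (160.0, 160.0, 160.0))


class PrunedFront(Front):
    """A neuron that grows radial dendrites, receives synapses from bouton
    somata placed alongside, then prunes every dendrite whose branch carries
    fewer synapses than the threshold."""

    attributes = ("role",)
    params = RetractionParams()

    def manage_front(self, constellation):
        p = self.params
        cyc = constellation.cycle
        if self.is_sphere():
            if cyc == 1:
                self._grow_roots(constellation, p)
            elif cyc == self._prune_cycle(p):
                self._prune(constellation, p)
                self.disable(constellation)
            return
        if self.num_children == 0 and cyc < self._prune_cycle(p) - 1:
            self._extend_straight(constellation, p)
        else:
            self.disable(constellation)

    def _prune_cycle(self, p):
        # roots at cycle 1, extensions until chains are complete, boutons
        # synapse on the following cycle, pruning on the one after
        return p.fronts_per_dendrite + 2

    def _grow_roots(self, constellation, p):
        centre = self.orig
        for k in range(p.n_dendrites):
            ang = 2.0 * np.pi * k / p.n_dendrites
            direction = np.array([np.cos(ang), np.sin(ang), 0.0])
            pos = centre + direction * (p.soma_radius + p.segment_length)
            child = self.add_child(constellation, pos,
                                   radius=p.dendrite_radius)
            child.role = float(k + 1)   # dendrite index, 1-based
        # stay active: the soma runs the pruning rule later

    def _extend_straight(self, constellation, p):
        pos = self.end + self.heading() * p.segment_length
        try:
            child = self.add_child(constellation, pos)
        except _GROWTH_ERRORS:
            self.disable(constellation)
            return
        child.role = self.role
        self.disable(constellation)

    def _prune(self, constellation, p):
        for root in list(self.children()):
            if root.is_retracted():
                continue
            n_syn = constellation.count_synapses(root, branch=True)
            if n_syn < p.synapse_threshold:
                self.retract_branch(constellation, root)


class BoutonFront(Front):
    """Presynaptic boutons: tiny somata that synapse onto the nearest
    dendrite front within reach, then go quiet."""

    params = RetractionParams()

    def manage_front(self, constellation):
        store = constellation.store
        best, best_gap = None, None
        for fid in store.iter_ids():
            other = store.get_front(fid)
            if not isinstance(other, PrunedFront) or other.is_sphere():
                continue
            from .environment import capsule_gap
            gap = capsule_gap(self, other)
            if best_gap is None or gap < best_gap:
                best, best_gap = other, gap
        if best is not None:
            try:
                self.make_synapse(constellation, best, weight=1.0,
                                  max_distance=0.5)
            except Exception:
                pass
        self.disable(constellation)


def retraction_demo(seed=0, params=None, db_path=None, **sim_kwargs):
    """Grow the pruning scene and run it to just past the pruning cycle.

    Dendrite k (1-based) is assigned ``synapse_counts[k-1]`` boutons; after
    the pruning cycle every dendrite with fewer than ``synapse_threshold``
    synapses is gone.  Returns the Simulator.
    """
    p = params or RetractionParams()

    class _Pruned(PrunedFront):
        params = p
    _Pruned.__name__ = "PrunedFront"

    class _Bouton(BoutonFront):
        params = p
    _Bouton.__name__ = "BoutonFront"

    sim = Simulator([_Pruned, _Bouton], volume=p.volume, num_cores=2,
                    seed=seed, db_path=db_path, **sim_kwargs)
    centre = (np.asarray(p.volume[0]) + np.asarray(p.volume[1])) / 2.0
    sim.add_neurons(_Pruned, "target", n=1, origins=[centre],
                    soma_radius=p.soma_radius)
    # grow roots + chains (cycles 1 .. fronts_per_dendrite)
    sim.simulation_loop(p.fronts_per_dendrite)
    # place boutons above the dendrites with the prescribed counts
    positions = []
    gap = 0.3
    z_off = p.dendrite_radius + p.bouton_radius + gap
    for k in range(p.n_dendrites):
        count = p.synapse_counts[k]
        ang = 2.0 * np.pi * k / p.n_dendrites
        direction = np.array([np.cos(ang), np.sin(ang), 0.0])
        reach = p.soma_radius + p.fronts_per_dendrite * p.segment_length
        for j in range(count):
            radial = (p.soma_radius + 2.0
                      + (j + 0.5) * (reach - p.soma_radius - 3.0)
                      / max(count, 1))
            z = z_off if j % 2 == 0 else -z_off
            positions.append(centre + direction * radial
                             + np.array([0.0, 0.0, z]))
    if positions:
        sim.add_neurons(_Bouton, "bouton", n=len(positions),
                        origins=positions, soma_radius=p.bouton_radius)
        sim.simulation_loop(1)   # boutons synapse
    sim.simulation_loop(2)       # pruning cycle + one settling cycle
    return sim
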