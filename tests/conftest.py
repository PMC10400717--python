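"""Shared fixtures: small scripted engines and scene builders."""

import numpy as np
import pytest

from frontsim.engine import Simulator
from frontsim.fronts import Front


class ScriptedFront(Front):
    """A front whose growth is driven from test code, not per-cycle rules."""

    def manage_front(self, constellation):
        pass


class DisabledFront(Front):
    def manage_front(self, constellation):
        self.disable(constellation)


@pytest.fixture()
def small_sim():
    """A 100 um box engine with a scripted front class (serial)."""
    sim = Simulator([ScriptedFront], volume=(100.0, 100.0, 100.0),
                    seed=1, capacity=2000)
    yield sim
    sim.destruction()


def grow_soma(sim, pos=(50, 50, 50), radius=10.0, cls=None):
    cls = cls or sim.store.front_classes[0]
    (soma,) = sim.add_neurons(cls, "n", n=1, origins=[np.asarray(pos,
                                                                 float)],
                              soma_radius=radius)
    return soma


def structurally_adjacent(fa, ida, fb, idb, tol=1e-6):
    """Contacts that are tree structure, not collisions: parent-child,
    siblings sharing a branch-point anchor, and a cylinder abutting a soma
    with its endpoint on the soma surface (trailing axons, filipodia)."""
    if fa.parent == idb or fb.parent == ida:
        return True
    if np.allclose(fa.orig, fb.orig, atol=tol):
        return True
    for sphere, cyl in ((fa, fb), (fb, fa)):
        if sphere.is_sphere() and cyl.is_cylinder():
            for p in (cyl.orig, cyl.end):
                if abs(np.linalg.norm(p - sphere.orig)
                       - sphere.radius) <= tol:
                    return True
    return False


def assert_no_illegal_overlaps(store):
    """Brute-force all-pairs sweep: no two live, non-adjacent fronts may
    overlap (the simulator's core guarantee)."""
    from frontsim.geometry import segment_distance_batch

    ids = list(store.iter_ids())
    fr = [store.get_front(f) for f in ids]
    if len(fr) < 2:
        return
    P0 = np.array([f.orig for f in fr])
    P1 = np.array([f.end for f in fr])
    R = np.array([f.radius for f in fr])
    for i in range(len(fr) - 1):
        d = segment_distance_batch(P0[i], P1[i], P0[i + 1:], P1[i + 1:])
        for h in np.nonzero(d < R[i] + R[i + 1:] - 1e-9)[0]:
            j = i + 1 + h
            assert structurally_adjacent(fr[i], ids[i], fr[j], ids[j]), \
                f"illegal overlap between {ids[i]} and {ids[j]}"


def chain(sim, parent, direction, step, n, radius=None):
    """Grow a straight chain of n cylinder fronts from `parent`."""
    con = sim.constellation
    direction = np.asarray(direction, float)
    direction = direction / np.linalg.norm(direction)
    out = []
    for _ in range(n):
        anchor = parent.orig if parent.is_sphere() else parent.end
        offset = step + (parent.radius if parent.is_sphere() else 0.0)
        child = con.add_child(parent, anchor + direction * offset,
                              radius=radius)
        out.append(child)
        parent = child
    return out
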