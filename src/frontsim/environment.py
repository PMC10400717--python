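"""Diffusible substrate cues and synapses.

Substrate sources are point deposits of a cue that spreads by diffusion;
growing fronts sense the local concentration either deterministically or as
a Poisson-distributed molecule count (the stochastic sampling growth cones
actually experience).  The concentration of a source of ``n_mol`` molecules
deposited at cycle ``b`` is the instantaneous point-source solution

    C(r, t) = n_mol * (4*pi*D*t)**-1.5 * exp(-r**2 / (4*D*t)),

with t = cycle - b in cycles (t = 0 is read as t = 1: deposits are sensed
from their birth cycle on) and D in um^2/cycle; contributions of multiple
sources add.  The stochastic sample is Poisson(C * v) with a probe volume of
v = 1 um^3.

Synapses link a pre- and a post-synaptic front that grew close to each
other.  They do not occupy space (no grid registration), carry a weight, and
disappear when either endpoint is retracted.  A simple Hebbian rate-product
rule is provided for weight updates.
"""

from __future__ import annotations

import math

import numpy as np

from . import _shm
from .errors import OverflowError, UsageError
from .fronts import pack_id, unpack_id
from .geometry import segment_segment_distance


class _SectionedRecords:
    """Fixed-capacity float record array split into per-writer sections.

    The same private-section discipline as the fronts store: writer `pid`
    allocates only inside its own slice; everyone may read everywhere.
    Index 0 is unused.
    """

    def __init__(self, n_cols, capacity, num_sections=1, shared=False,
                 name="records"):
        self.n_cols = n_cols
        self.num_sections = num_sections
        self.section_size = max(capacity // num_sections, 1)
        self.capacity = self.section_size * num_sections
        self.name = name
        self.data = _shm.zeros((self.capacity + 1, n_cols), "float64", shared)
        self.used = _shm.zeros(self.capacity + 1, "int64", shared)
        self._counters = _shm.zeros(num_sections + 1, "int64", shared)

    def allocate(self, pid=1):
        used = int(self._counters[pid])
        if used >= self.section_size:
            raise OverflowError(f"{self.name} section of core {pid}")
        self._counters[pid] = used + 1
        idx = (pid - 1) * self.section_size + 1 + used
        self.used[idx] = 1
        return idx

    def indices(self):
        return [int(i) for i in np.nonzero(self.used[1:])[0] + 1]


# Substrate columns: x, y, z, n_mol, D, birth_cycle, name_id
_SUB_COLS = 7
# Synapse columns: pre(packed), post(packed), weight, birth, death
_SYN_COLS = 5


class SubstrateTable(_SectionedRecords):
    """Shared storage of substrate point sources."""

    def __init__(self, capacity=2000, num_sections=1, shared=False,
                 names=()):
        super().__init__(_SUB_COLS, capacity, num_sections, shared,
                         name="substrate")
        self.names = list(names)

    def name_id(self, name):
        if name not in self.names:
            raise UsageError(
                f"substrate name {name!r} was not declared up front; "
                "pass it in substrate_names at simulator construction")
        return self.names.index(name)

    def add(self, pid, name, position, n_mol, diffusion, cycle):
        if n_mol < 0 or diffusion <= 0:
            raise UsageError("need n_mol >= 0 and diffusion constant > 0")
        nid = self.name_id(name)
        idx = self.allocate(pid)
        self.data[idx] = (*position, n_mol, diffusion, cycle, nid)
        return idx

    def sources(self):
        """(position, n_mol, D, birth_cycle) tuples of all sources."""
        out = []
        for i in self.indices():
            row = self.data[i]
            out.append((np.array(row[0:3]), float(row[3]), float(row[4]),
                        int(row[5])))
        return out

    def record(self, idx):
        """Storage tuple (name, x, y, z, n_mol, D, birth) for the trace."""
        row = self.data[idx]
        return (self.names[int(row[6])], float(row[0]), float(row[1]),
                float(row[2]), float(row[3]), float(row[4]), int(row[5]))


class SynapseTable(_SectionedRecords):
    """Shared storage of synapses (pre/post packed FrontIDs + weight)."""

    def __init__(self, capacity=2000, num_sections=1, shared=False):
        super().__init__(_SYN_COLS, capacity, num_sections, shared,
                         name="synapses")

    def add(self, pid, pre_packed, post_packed, weight, cycle):
        idx = self.allocate(pid)
        self.data[idx] = (pre_packed, post_packed, weight, cycle, 0)
        return idx

    def is_live(self, idx):
        return bool(self.used[idx]) and self.data[idx, 4] == 0

    def live_indices(self):
        return [i for i in self.indices() if self.data[i, 4] == 0]

    def endpoints(self, idx):
        return (unpack_id(int(self.data[idx, 0])),
                unpack_id(int(self.data[idx, 1])))

    def kill(self, idx, cycle):
        self.data[idx, 4] = cycle

    def weight(self, idx):
        return float(self.data[idx, 2])

    def set_weight(self, idx, w):
        self.data[idx, 2] = w

    def record(self, idx):
        row = self.data[idx]
        pre = unpack_id(int(row[0]))
        post = unpack_id(int(row[1]))
        return (pre.row, pre.index, post.row, post.index, float(row[2]),
                int(row[3]), int(row[4]))


# ---------------------------------------------------------------------------
# Concentration sampling.

def concentration_at(point, sources, cycle):
    """Deterministic summed concentration (molecules / um^3) at `point`."""
    p = np.asarray(point, dtype=float)
    total = 0.0
    for pos, n_mol, diff, birth in sources:
        t = max(cycle - birth, 1)
        r2 = float(np.sum((p - pos) ** 2))
        denom = (4.0 * math.pi * diff * t) ** 1.5
        total += n_mol / denom * math.exp(-r2 / (4.0 * diff * t))
    return total


def sample_concentration(point, sources, cycle, rng=None, stochastic=False,
                         probe_volume=1.0):
    """Concentration at `point`: the model mean, or a Poisson molecule count.

    Stochastic mode emulates the shot noise a growth cone experiences when
    counting the few molecules inside a ~1 um^3 sensing volume.
    """
    c = concentration_at(point, sources, cycle)
    if not stochastic:
        return c
    if rng is None:
        raise UsageError("stochastic sampling needs an rng")
    return int(rng.poisson(c * probe_volume))


# ---------------------------------------------------------------------------
# Synapse-level operations (engine-independent pieces).

def capsule_gap(front_a, front_b):
    """Surface-to-surface distance between two fronts (negative = overlap)."""
    d = segment_segment_distance(front_a.orig, front_a.end,
                                 front_b.orig, front_b.end)
    return d - front_a.radius - front_b.radius


def check_synapse(table: SynapseTable, pre, post, max_distance):
    """Validate a prospective synapse; raises UsageError on violation."""
    if pre.id == post.id:
        raise UsageError("pre and post fronts must differ")
    if pre.is_retracted() or post.is_retracted():
        raise UsageError("cannot synapse onto a retracted front")
    gap = capsule_gap(pre, post)
    if gap > max_distance:
        raise UsageError(
            f"fronts are {gap:.2f} um apart (surface-to-surface), beyond "
            f"the {max_distance} um synapse range")
    pp, qq = pack_id(pre.id), pack_id(post.id)
    for idx in table.live_indices():
        if (int(table.data[idx, 0]), int(table.data[idx, 1])) == (pp, qq):
            raise UsageError("synapse between this pre/post pair exists")


def count_synapses(table: SynapseTable, front_ids):
    """Live synapses with pre or post on any of the given FrontIDs."""
    wanted = {pack_id(f) for f in front_ids}
    n = 0
    for idx in table.live_indices():
        if (int(table.data[idx, 0]) in wanted
                or int(table.data[idx, 1]) in wanted):
            n += 1
    return n


def hebbian_update(weight, pre_rate, post_rate, learning_rate):
    """Rate-product Hebbian step: w' = w + eta * pre_rate * post_rate."""
    if pre_rate < 0 or post_rate < 0:
        raise UsageError("firing rates must be non-negative")
    return weight + learning_rate * pre_rate * post_rate
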