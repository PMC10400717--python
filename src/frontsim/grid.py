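"""Uniform 3D grid index for locality-restricted collision detection.

The lattice spans the simulation volume with spacing ``grid_step`` (default
20 um).  Every front is registered at one or more lattice points (*gids*,
positive integers); a collision query for a candidate capsule only tests
fronts registered at the candidate's gids and their 26 neighbours.

Allocation rule.  A front is registered at every lattice point whose Voronoi
cell (the closed cube of side grid_step centred on the point) intersects the
axis-aligned bounding box of the front's axis segment, pruned to lattice
points within (sqrt(3)/2)*grid_step of the axis.  This guarantees that the
nearest lattice point of *any* point on the axis is registered; hence for two
colliding capsules with r1 + r2 < grid_step the registered sets lie within
one Chebyshev step of each other and the neighbour search is exhaustive —
the grid query provably agrees with a brute-force all-pairs sweep.  Fronts
thicker than grid_step/2 trigger a configuration warning.

Storage.  ``grid`` maps gid -> start of a linked block chain in
``grid_extra``; blocks have a default size of 10 entries and are allocated
in per-writer private sections.  When a block overflows, its last slot is
converted into a link to a freshly allocated block and the entry that
occupied it moves to the new block.
"""

from __future__ import annotations

import math
import warnings

import numpy as np

from . import _shm
from .errors import OverflowError, UsageError, VolumeError
from .fronts import FLAG_RETRACTED, _I_FLAGS, unpack_id
from .geometry import segment_segment_distance


class GridConfig:
    """Lattice geometry: spacing, volume bounds and derived dimensions."""

    def __init__(self, volume_min, volume_max, grid_step=20.0, block_size=10):
        self.vmin = np.asarray(volume_min, dtype=float)
        self.vmax = np.asarray(volume_max, dtype=float)
        if np.any(self.vmax <= self.vmin):
            raise UsageError("volume_max must exceed volume_min on all axes")
        if grid_step <= 0:
            raise UsageError("grid_step must be positive")
        self.grid_step = float(grid_step)
        self.block_size = int(block_size)
        if self.block_size < 2:
            raise UsageError("block_size must be at least 2")
        extent = self.vmax - self.vmin
        # lattice points at vmin + i*grid_step, covering the whole volume
        self.dims = tuple(int(math.ceil(e / self.grid_step)) + 1
                          for e in extent)
        self.n_gids = self.dims[0] * self.dims[1] * self.dims[2]

    def gid_from_ixyz(self, ix, iy, iz):
        nx, ny, _ = self.dims
        return 1 + ix + nx * (iy + ny * iz)

    def ixyz_from_gid(self, gid):
        nx, ny, _ = self.dims
        r = gid - 1
        ix = r % nx
        r //= nx
        return ix, r % ny, r // ny

    def lattice_point(self, gid):
        ix, iy, iz = self.ixyz_from_gid(gid)
        return self.vmin + np.array([ix, iy, iz], dtype=float) * self.grid_step

    def contains(self, point):
        p = np.asarray(point, dtype=float)
        return bool(np.all(p >= self.vmin) and np.all(p <= self.vmax))


def front_to_gids(orig, end, radius, config: GridConfig):
    """Sorted gids a capsule must be registered at (see module docstring)."""
    orig = np.asarray(orig, dtype=float)
    end = np.asarray(end, dtype=float)
    if not (config.contains(orig) and config.contains(end)):
        raise VolumeError(f"front geometry {orig}..{end} outside the volume")
    if radius > config.grid_step / 2.0 + 1e-9:
        warnings.warn(
            f"front radius {radius} >= grid_step/2 "
            f"({config.grid_step / 2.0}); collision search may miss pairs — "
            "decrease the radius or increase grid_step", stacklevel=2)
    s = config.grid_step
    lo = np.minimum(orig, end) - config.vmin
    hi = np.maximum(orig, end) - config.vmin
    ilo = np.maximum(np.ceil(lo / s - 0.5 - 1e-9), 0).astype(int)
    ihi = np.minimum(np.floor(hi / s + 0.5 + 1e-9),
                     np.array(config.dims) - 1).astype(int)
    axes = [np.arange(ilo[k], ihi[k] + 1) for k in range(3)]
    pts = (np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1)
           .reshape(-1, 3))
    coords = config.vmin + pts * s
    # prune to lattice points near the axis segment
    thresh = (math.sqrt(3.0) / 2.0) * s + 1e-9
    keep = []
    for k in range(len(pts)):
        d = segment_segment_distance(coords[k], coords[k], orig, end)
        if d <= thresh:
            keep.append(pts[k])
    if not keep:  # cannot happen: the nearest lattice point always qualifies
        raise AssertionError("empty gid set for an in-volume front")
    gids = sorted(config.gid_from_ixyz(ix, iy, iz) for ix, iy, iz in keep)
    return gids


def neighbors(gid, config: GridConfig):
    """The up-to-26 lattice points at Chebyshev distance 1, volume-clipped."""
    ix, iy, iz = config.ixyz_from_gid(gid)
    nx, ny, nz = config.dims
    out = []
    for dx in (-1, 0, 1):
        x = ix + dx
        if not 0 <= x < nx:
            continue
        for dy in (-1, 0, 1):
            y = iy + dy
            if not 0 <= y < ny:
                continue
            for dz in (-1, 0, 1):
                z = iz + dz
                if not 0 <= z < nz:
                    continue
                if dx == 0 and dy == 0 and dz == 0:
                    continue
                out.append(config.gid_from_ixyz(x, y, z))
    return out


def search_region(gids, config: GridConfig):
    """gids plus all their neighbours, sorted and deduplicated."""
    region = set(gids)
    for g in gids:
        region.update(neighbors(g, config))
    return sorted(region)


class GridIndexMap:
    """gid -> linked blocks of packed FrontIDs, with per-writer sections.

    ``grid[gid]`` is 0 (empty) or the start index of the first block in
    ``extra``.  Within a block, slots hold packed FrontIDs (0 = empty); the
    last slot may instead hold a negative link ``-next_block_start``.
    Freed chains are recycled through per-writer free lists in single-writer
    (serial) mode only.
    """

    def __init__(self, config: GridConfig, extra_capacity=None,
                 num_sections=1, shared=False):
        self.config = config
        self.num_sections = num_sections
        self.shared = shared
        bs = config.block_size
        if extra_capacity is None:
            extra_capacity = max(50 * bs * num_sections, 20_000)
        self.blocks_per_section = extra_capacity // (bs * num_sections)
        self.section_blocks = self.blocks_per_section
        self.extra_capacity = self.blocks_per_section * bs * num_sections
        self.grid = _shm.zeros(config.n_gids + 1, "int64", shared)
        self.extra = _shm.zeros(self.extra_capacity + 1, "int64", shared)
        self._block_counters = _shm.zeros(num_sections + 1, "int64", shared)
        self._free_blocks = [[] for _ in range(num_sections + 1)]
        self._reclaim = not shared

    # -- block allocation ---------------------------------------------------
    def _alloc_block(self, pid):
        if self._reclaim and self._free_blocks[pid]:
            return self._free_blocks[pid].pop()
        used = int(self._block_counters[pid])
        if used >= self.blocks_per_section:
            raise OverflowError(f"grid_extra section of core {pid}")
        self._block_counters[pid] = used + 1
        start = ((pid - 1) * self.blocks_per_section + used) \
            * self.config.block_size + 1
        return start

    def _free_block(self, start):
        if not self._reclaim:
            return
        pid = (start - 1) // (self.blocks_per_section
                              * self.config.block_size) + 1
        self._free_blocks[pid].append(start)

    # -- chain traversal ----------------------------------------------------
    def entries_at(self, gid):
        """Packed FrontIDs registered at `gid`, in block order."""
        out = []
        block = int(self.grid[gid])
        bs = self.config.block_size
        while block:
            nxt = 0
            for k in range(bs):
                v = int(self.extra[block + k])
                if v == 0:
                    return out
                if v < 0:
                    nxt = -v
                    break
                out.append(v)
            block = nxt
        return out

    def register(self, gid, packed_fid, pid=1):
        """Append a front at `gid`, allocating/linking blocks as needed."""
        if packed_fid <= 0:
            raise UsageError("invalid packed front id")
        bs = self.config.block_size
        block = int(self.grid[gid])
        if block == 0:
            block = self._alloc_block(pid)
            self.extra[block:block + bs] = 0
            self.grid[gid] = block
            self.extra[block] = packed_fid
            return
        while True:
            for k in range(bs):
                v = int(self.extra[block + k])
                if v == packed_fid:
                    raise UsageError(
                        f"front already registered at gid {gid}")
                if v == 0:
                    self.extra[block + k] = packed_fid
                    return
                if v < 0:
                    block = -v
                    break
            else:
                # block full of entries: convert the last slot into a link
                new_block = self._alloc_block(pid)
                self.extra[new_block:new_block + bs] = 0
                moved = int(self.extra[block + bs - 1])
                self.extra[new_block] = moved
                self.extra[new_block + 1] = packed_fid
                self.extra[block + bs - 1] = -new_block
                return

    def deregister(self, gid, packed_fid):
        """Remove a front from `gid`, back-filling with the chain's last
        entry so entries stay contiguous."""
        bs = self.config.block_size
        first = int(self.grid[gid])
        target = None        # (block, slot) of the entry being removed
        last = None          # (block, slot) of the last entry in the chain
        prev_block = None    # block whose link points at `block`
        block = first
        while block:
            nxt = 0
            for k in range(bs):
                v = int(self.extra[block + k])
                if v == 0:
                    break
                if v < 0:
                    nxt = -v
                    break
                if v == packed_fid:
                    target = (block, k)
                last = (block, k)
            if nxt == 0:
                break
            prev_block = block
            block = nxt
        if target is None:
            raise UsageError(f"front not registered at gid {gid}")
        lb, lk = last
        self.extra[target[0] + target[1]] = int(self.extra[lb + lk])
        self.extra[lb + lk] = 0
        if lk == 0 and lb != first:
            # the trailing block emptied: drop the link to it
            self.extra[prev_block + bs - 1] = 0
            self._free_block(lb)
        elif lk == 0 and lb == first:
            self.grid[gid] = 0
            self._free_block(lb)

    # -- queries ------------------------------------------------------------
    def candidates_in_region(self, gids_region):
        """Packed FrontIDs registered anywhere in the region, in ascending
        gid then block order, deduplicated preserving first occurrence."""
        seen = set()
        out = []
        for g in gids_region:
            for v in self.entries_at(g):
                if v not in seen:
                    seen.add(v)
                    out.append(v)
        return out

    def occupancy_counts(self):
        """dict gid -> number of fronts registered there (occupied only)."""
        counts = {}
        occupied = np.nonzero(self.grid[1:])[0] + 1
        for g in occupied:
            n = len(self.entries_at(int(g)))
            if n:
                counts[int(g)] = n
        return counts


def collision_query(store, index_map: GridIndexMap, orig, end, radius,
                    exclude=(), mode="first", gids=None, anchor=None):
    """Test a candidate capsule against registered fronts near it.

    A collision is a *strict* overlap: segment distance < sum of radii
    (touching capsules do not collide).  ``exclude`` is an iterable of packed
    FrontIDs never tested (the candidate's parent, self during migration...).
    ``anchor`` is the candidate's attachment point: fronts whose own orig or
    end coincides with it (sibling branches sprouting from the same branch
    point) are in structural contact, not collision, and are skipped.
    mode="first" returns the first colliding packed FrontID in deterministic
    scan order (ascending gid, block order) or None; mode="all" returns the
    list of all colliding packed FrontIDs.
    """
    config = index_map.config
    if gids is None:
        gids = front_to_gids(orig, end, radius, config)
    region = search_region(gids, config)
    excluded = set(exclude)
    hits = []
    for packed in index_map.candidates_in_region(region):
        if packed in excluded:
            continue
        fid = unpack_id(packed)
        if store._i[fid.row][fid.index, _I_FLAGS] & FLAG_RETRACTED:
            continue
        other = store.get_front(fid)
        if anchor is not None and shares_anchor(other, anchor):
            continue
        d = segment_segment_distance(orig, end, other.orig, other.end)
        # strict overlap only: exact touching is not a collision, so give
        # the comparison a small numeric guard band
        if d < radius + other.radius - 1e-9:
            if mode == "first":
                return packed
            hits.append(packed)
    return None if mode == "first" else hits


def shares_anchor(front, anchor, tol=1e-9):
    """True if the front's orig or end coincides with the anchor point."""
    a = np.asarray(anchor, dtype=float)
    return (bool(np.all(np.abs(front.orig - a) <= tol))
            or (front.is_cylinder()
                and bool(np.all(np.abs(front.end - a) <= tol))))


def grid_stats(index_map: GridIndexMap, live_fronts=None):
    """Occupancy metrics of the grid index.

    Returns the five standard measures: mean gids per front, fraction of
    lattice points occupied, fractions of occupied points holding 1-5 and
    1-10 fronts, and the largest number of fronts at a single point.
    """
    counts = index_map.occupancy_counts()
    n_gids = index_map.config.n_gids
    n_occupied = len(counts)
    total_regs = sum(counts.values())
    if live_fronts is None:
        distinct = set()
        for g in counts:
            distinct.update(index_map.entries_at(g))
        live_fronts = len(distinct)
    stats = {
        "mean_gids_per_front": (total_regs / live_fronts
                                if live_fronts else 0.0),
        "occupancy": n_occupied / n_gids,
        "frac_occupied_1_5": (sum(1 for n in counts.values() if n <= 5)
                              / n_occupied if n_occupied else 0.0),
        "frac_occupied_1_10": (sum(1 for n in counts.values() if n <= 10)
                               / n_occupied if n_occupied else 0.0),
        "max_fronts_per_gid": max(counts.values()) if counts else 0,
    }
    return stats
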