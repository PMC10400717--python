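"""The front data model: fixed-size records, the neuron tree, status flags.

A *front* is the elementary agent: a sphere (soma) or a capsule (cylinder
axis + radius).  Fronts of each ``Front`` subclass live in one fixed-capacity
array row of the :class:`FrontStore`; a :class:`FrontID` is the (row, index)
pair addressing that store, with index 0 reserved to mean empty.  The store
is subdivided into per-writer private sections so that, in parallel runs,
each core only ever allocates records in its own slice while reading
anywhere.

Children of a front are kept as an intrusive linked list
(``first_child`` / ``next_sibling``), matching the fixed-size record model;
retracted fronts are flagged and unlinked, never physically deleted.
"""

from __future__ import annotations

from typing import NamedTuple

import numpy as np

from . import _shm, geometry
from .errors import InsideParentError, OverflowError, UsageError

# ---------------------------------------------------------------------------
# FrontID packing: (row, index) <-> single int64, 0 == null.

_ROW_SHIFT = 32
_IDX_MASK = (1 << _ROW_SHIFT) - 1


class FrontID(NamedTuple):
    """Address of a front: subclass-array row and index within that row.

    Index 0 is reserved: it marks an unused or empty slot everywhere.
    """

    row: int
    index: int

    def packed(self):
        return (self.row << _ROW_SHIFT) | self.index

    def __repr__(self):
        return f"({self.row},{self.index})"


NULL_ID = 0


def pack_id(fid: FrontID) -> int:
    return (fid.row << _ROW_SHIFT) | fid.index


def unpack_id(packed: int) -> FrontID:
    return FrontID(packed >> _ROW_SHIFT, packed & _IDX_MASK)


# ---------------------------------------------------------------------------
# Status flags.

FLAG_ACTIVE = 1       # scheduled for manage_front dispatch
FLAG_GROWING = 2      # dispatched in the first (growing) category
FLAG_MIGRATING = 4    # dispatched in the second (migrating) category
FLAG_RETRACTED = 8
FLAG_FILIPODIUM = 16  # this front is the leading filipodium of its soma
FLAG_TRAILING_AXON = 32   # soma: deposits an axon front on each migration
FLAG_AXON_FRONT = 64      # this front is part of a trailing axon chain

# Shape codes stored in the record.
SHAPE_EMPTY = 0
SHAPE_SPHERE = 1
SHAPE_CYLINDER = 2

# Float columns.
_F_OX, _F_OY, _F_OZ, _F_EX, _F_EY, _F_EZ, _F_RADIUS, _F_PATH = range(8)
_N_FLOAT_BASE = 8

# Int columns.
(_I_SHAPE, _I_ORDER, _I_PARENT, _I_FIRST_CHILD, _I_NEXT_SIB, _I_SOMA,
 _I_NUM_CHILDREN, _I_FLAGS, _I_BIRTH, _I_DEATH, _I_SWC, _I_FILI,
 _I_AXON_TIP) = range(13)
_N_INT = 13


def _float_attr(col):
    def fget(self):
        return float(self._store._f[self._row][self._idx, col])

    def fset(self, value):
        self._store._f[self._row][self._idx, col] = value

    return property(fget, fset)


class Front:
    """A single sphere or capsule agent; a lightweight proxy onto the store.

    Subclasses implement :meth:`manage_front` (the growth rule run once per
    cycle while the front is active) and may declare extra per-front
    ``attributes`` (a tuple of names, stored as float slots fixed at subclass
    definition time).
    """

    #: extra float-valued slots present on every instance of the subclass
    attributes: tuple = ()

    def __init__(self, store, row, idx):
        object.__setattr__(self, "_store", store)
        object.__setattr__(self, "_row", row)
        object.__setattr__(self, "_idx", idx)

    # -- identity -----------------------------------------------------------
    @property
    def id(self) -> FrontID:
        return FrontID(self._row, self._idx)

    def __eq__(self, other):
        return (isinstance(other, Front) and self._row == other._row
                and self._idx == other._idx and self._store is other._store)

    def __hash__(self):
        return hash((self._row, self._idx))

    def __repr__(self):
        kind = "sphere" if self.is_sphere() else "cylinder"
        return f"<{type(self).__name__} ({self._row},{self._idx}) {kind}>"

    # -- geometry -----------------------------------------------------------
    @property
    def orig(self):
        return np.array(self._store._f[self._row][self._idx, _F_OX:_F_OZ + 1])

    @orig.setter
    def orig(self, value):
        self._store._f[self._row][self._idx, _F_OX:_F_OZ + 1] = value

    @property
    def end(self):
        return np.array(self._store._f[self._row][self._idx, _F_EX:_F_EZ + 1])

    @end.setter
    def end(self, value):
        self._store._f[self._row][self._idx, _F_EX:_F_EZ + 1] = value

    radius = _float_attr(_F_RADIUS)
    path_length = _float_attr(_F_PATH)

    def is_sphere(self):
        return self._int(_I_SHAPE) == SHAPE_SPHERE

    def is_cylinder(self):
        return self._int(_I_SHAPE) == SHAPE_CYLINDER

    def length(self):
        """Axis length in micrometres (0 for a soma)."""
        if self.is_sphere():
            return 0.0
        return float(np.linalg.norm(self.end - self.orig))

    def heading(self):
        """Unit vector along the axis (cylinders only)."""
        if self.is_sphere():
            raise UsageError("a soma has no heading")
        d = self.end - self.orig
        return d / np.linalg.norm(d)

    # -- record fields ------------------------------------------------------
    def _int(self, col):
        return int(self._store._i[self._row][self._idx, col])

    def _set_int(self, col, value):
        self._store._i[self._row][self._idx, col] = value

    @property
    def order(self):
        return self._int(_I_ORDER)

    @property
    def parent(self):
        p = self._int(_I_PARENT)
        return unpack_id(p) if p else None

    @property
    def soma_id(self):
        return unpack_id(self._int(_I_SOMA))

    @property
    def num_children(self):
        return self._int(_I_NUM_CHILDREN)

    @property
    def flags(self):
        return self._int(_I_FLAGS)

    @property
    def birth_cycle(self):
        return self._int(_I_BIRTH)

    @property
    def death_cycle(self):
        return self._int(_I_DEATH)

    @property
    def swc_type(self):
        return self._int(_I_SWC)

    def has_flag(self, flag):
        return bool(self._int(_I_FLAGS) & flag)

    def is_active(self):
        return self.has_flag(FLAG_ACTIVE) and not self.has_flag(FLAG_RETRACTED)

    def is_retracted(self):
        return self.has_flag(FLAG_RETRACTED)

    def is_terminal(self):
        return self.num_children == 0

    def children(self):
        """Child fronts in creation order."""
        out = []
        c = self._int(_I_FIRST_CHILD)
        while c:
            fid = unpack_id(c)
            out.append(self._store.get_front(fid))
            c = int(self._store._i[fid.row][fid.index, _I_NEXT_SIB])
        return out

    # -- growth API (delegates to the engine through the constellation) -----
    def add_child(self, constellation, new_pos, radius=None, swc_type=None,
                  role=None):
        return constellation.add_child(self, new_pos, radius=radius,
                                       swc_type=swc_type, role=role)

    def migrate_soma(self, constellation, new_pos):
        return constellation.migrate_soma(self, new_pos)

    def retract(self, constellation):
        return constellation.retract(self)

    def retract_branch(self, constellation, child):
        return constellation.retract_branch(self, child)

    def enable(self, constellation, growing=True, migrating=False):
        return constellation.enable(self, growing=growing,
                                    migrating=migrating)

    def disable(self, constellation):
        return constellation.disable(self)

    def solve_collision(self, constellation, new_pos, error, radius=None):
        return constellation.solve_collision(self, new_pos, error,
                                             radius=radius)

    def make_synapse(self, constellation, other, weight=1.0,
                     max_distance=0.5):
        return constellation.add_synapse(self, other, weight=weight,
                                         max_distance=max_distance)

    # -- sampling helpers mirroring the model-definition API ----------------
    def unit_heading_sample(self, constellation, max_angle=20.0):
        return geometry.unit_heading_sample(self.heading(), max_angle,
                                            constellation.rng)

    def unit_branching_sample(self, constellation, n, min_separation=None):
        return geometry.unit_branching_sample(n, constellation.rng,
                                              min_separation=min_separation)

    def taper(self, factor=0.9):
        return geometry.taper(self.radius, factor)

    # -- model hook ---------------------------------------------------------
    def manage_front(self, constellation):
        raise NotImplementedError(
            f"{type(self).__name__} must implement manage_front")


class FrontStore:
    """Fixed-capacity per-subclass front arrays with private writer sections.

    ``front_classes`` are Front subclasses, assigned rows 1..n in order.  The
    per-row capacity is split into ``num_sections`` equal private sections;
    writer *pid* 1 is the admin, pids 2.. are workers.  Index 0 of every row
    is never used.
    """

    def __init__(self, front_classes, capacity=20_000, num_sections=1,
                 shared=False):
        if capacity < num_sections:
            raise UsageError("capacity smaller than number of sections")
        self.front_classes = list(front_classes)
        self.num_rows = len(self.front_classes)
        self.num_sections = num_sections
        self.section_size = capacity // num_sections
        self.capacity = self.section_size * num_sections
        self.shared = shared
        self._classes = {}
        self._f = [None]
        self._i = [None]
        for row, cls in enumerate(self.front_classes, start=1):
            if not (isinstance(cls, type) and issubclass(cls, Front)):
                raise UsageError(f"{cls!r} is not a Front subclass")
            n_attr = len(cls.attributes)
            self._f.append(_shm.zeros((self.capacity + 1,
                                       _N_FLOAT_BASE + n_attr),
                                      "float64", shared))
            self._i.append(_shm.zeros((self.capacity + 1, _N_INT),
                                      "int64", shared))
            self._classes[row] = cls
            for k, name in enumerate(cls.attributes):
                setattr(cls, name, _float_attr(_N_FLOAT_BASE + k))
            cls._row = row
        # next-free offset (0-based within section) per (pid, row)
        self._counters = _shm.zeros((num_sections + 1, self.num_rows + 1),
                                    "int64", shared)

    # -- sections -----------------------------------------------------------
    def section_bounds(self, pid):
        """Inclusive (start, end) index range of writer `pid`'s section."""
        if not 1 <= pid <= self.num_sections:
            raise UsageError(f"writer pid {pid} out of range")
        start = (pid - 1) * self.section_size + 1
        return start, start + self.section_size - 1

    def allocate(self, pid, row):
        """Next free index in `pid`'s private section of `row`.

        Raises OverflowError naming the exhausted subclass array when the
        section is full.
        """
        used = int(self._counters[pid, row])
        if used >= self.section_size:
            name = self._classes[row].__name__
            raise OverflowError(f"fronts[{name}] section of core {pid}")
        self._counters[pid, row] = used + 1
        return (pid - 1) * self.section_size + 1 + used

    # -- access -------------------------------------------------------------
    def get_front(self, fid) -> Front:
        if isinstance(fid, int):
            fid = unpack_id(fid)
        return self._classes[fid.row](self, fid.row, fid.index)

    def class_for_row(self, row):
        return self._classes[row]

    def row_for_class(self, cls):
        for row, c in self._classes.items():
            if c is cls:
                return row
        raise UsageError(f"{cls.__name__} is not registered in this store")

    def is_used(self, fid: FrontID):
        return self._i[fid.row][fid.index, _I_SHAPE] != SHAPE_EMPTY

    def iter_ids(self, include_retracted=False):
        """All allocated FrontIDs in ascending (row, index) order."""
        for row in range(1, self.num_rows + 1):
            shape = self._i[row][:, _I_SHAPE]
            flags = self._i[row][:, _I_FLAGS]
            used = shape != SHAPE_EMPTY
            if not include_retracted:
                used = used & ((flags & FLAG_RETRACTED) == 0)
            for idx in np.nonzero(used)[0]:
                yield FrontID(row, int(idx))

    def live_count(self):
        n = 0
        for row in range(1, self.num_rows + 1):
            shape = self._i[row][:, _I_SHAPE]
            flags = self._i[row][:, _I_FLAGS]
            n += int(np.count_nonzero((shape != SHAPE_EMPTY)
                                      & ((flags & FLAG_RETRACTED) == 0)))
        return n

    def created_count(self):
        return int(sum(self._counters[pid, row]
                       for pid in range(1, self.num_sections + 1)
                       for row in range(1, self.num_rows + 1)))

    # -- record construction ------------------------------------------------
    def init_front(self, fid: FrontID, shape, orig, end, radius, *,
                   parent=None, soma=None, order=0, path_length=0.0,
                   birth_cycle=0, swc_type=0, flags=0):
        f = self._f[fid.row]
        i = self._i[fid.row]
        f[fid.index, _F_OX:_F_OZ + 1] = orig
        f[fid.index, _F_EX:_F_EZ + 1] = end if end is not None else orig
        f[fid.index, _F_RADIUS] = radius
        f[fid.index, _F_PATH] = path_length
        f[fid.index, _N_FLOAT_BASE:] = 0.0
        i[fid.index, :] = 0
        i[fid.index, _I_SHAPE] = shape
        i[fid.index, _I_ORDER] = order
        i[fid.index, _I_PARENT] = pack_id(parent) if parent else 0
        i[fid.index, _I_SOMA] = pack_id(soma) if soma else pack_id(fid)
        i[fid.index, _I_FLAGS] = flags
        i[fid.index, _I_BIRTH] = birth_cycle
        i[fid.index, _I_SWC] = swc_type


# ---------------------------------------------------------------------------
# Tree operations.

def make_child_geometry(parent: Front, new_pos, radius):
    """Geometry (orig, end, radius) of a prospective child cylinder.

    A cylinder child continues from the parent's *end*; a child of a soma is
    anchored on the soma surface, on the ray from the soma centre to
    ``new_pos``.  Raises InsideParentError if ``new_pos`` lies inside the
    parent's volume (or coincides with the anchor point, which would give a
    zero-length child).
    """
    new_pos = np.asarray(new_pos, dtype=float)
    if parent.is_sphere():
        centre = parent.orig
        d = new_pos - centre
        dist = float(np.linalg.norm(d))
        if dist <= parent.radius + 1e-12:
            raise InsideParentError(
                f"new_pos at distance {dist:.3f} lies inside the soma "
                f"(radius {parent.radius:.3f})")
        orig = centre + d * (parent.radius / dist)
    else:
        # inside the parent capsule?
        dist = geometry.segment_segment_distance(
            new_pos, new_pos, parent.orig, parent.end)
        anchor = parent.end
        if dist < parent.radius - 1e-12 or np.allclose(new_pos, anchor):
            raise InsideParentError(
                "new_pos lies inside the parent cylinder")
        orig = anchor
    return orig, new_pos, radius


def attach_child(store: FrontStore, parent: Front, child: Front):
    """Link a freshly allocated child into the tree.

    Appends to the parent's child list (creation order), increments
    num_children, and sets the child's order, soma and accumulated
    path_length.
    """
    i_p = store._i[parent._row]
    i_c = store._i[child._row]
    packed_child = pack_id(child.id)
    # append to the intrusive child list
    c = int(i_p[parent._idx, _I_FIRST_CHILD])
    if c == 0:
        i_p[parent._idx, _I_FIRST_CHILD] = packed_child
    else:
        while True:
            fid = unpack_id(c)
            nxt = int(store._i[fid.row][fid.index, _I_NEXT_SIB])
            if nxt == 0:
                store._i[fid.row][fid.index, _I_NEXT_SIB] = packed_child
                break
            c = nxt
    i_p[parent._idx, _I_NUM_CHILDREN] += 1
    i_c[child._idx, _I_PARENT] = pack_id(parent.id)
    i_c[child._idx, _I_ORDER] = parent.order + 1
    soma = parent.id if parent.is_sphere() else parent.soma_id
    i_c[child._idx, _I_SOMA] = pack_id(soma)
    seg = child.end - child.orig
    i_c = store._f[child._row]
    i_c[child._idx, _F_PATH] = (parent.path_length
                                + float(np.linalg.norm(seg)))


def unlink_child(store: FrontStore, child: Front):
    """Remove `child` from its parent's child list and decrement the count."""
    parent = child.parent
    if parent is None:
        return
    packed = pack_id(child.id)
    i_p = store._i[parent.row]
    c = int(i_p[parent.index, _I_FIRST_CHILD])
    prev = None
    while c:
        if c == packed:
            nxt = int(store._i[child._row][child._idx, _I_NEXT_SIB])
            if prev is None:
                i_p[parent.index, _I_FIRST_CHILD] = nxt
            else:
                store._i[prev.row][prev.index, _I_NEXT_SIB] = nxt
            store._i[child._row][child._idx, _I_NEXT_SIB] = 0
            i_p[parent.index, _I_NUM_CHILDREN] -= 1
            return
        prev = unpack_id(c)
        c = int(store._i[prev.row][prev.index, _I_NEXT_SIB])
    raise UsageError("child not found in parent's child list")


def collect_branch(store: FrontStore, front: Front):
    """The front and all its descendants, depth-first, as FrontIDs."""
    out = []
    stack = [front]
    while stack:
        f = stack.pop()
        out.append(f.id)
        stack.extend(reversed(f.children()))
    return out


def mark_retracted(store: FrontStore, fid: FrontID, cycle: int):
    """Flag a front retracted, stamp the death cycle and unlink it.

    Grid deregistration is the engine's job (done serially at end of cycle).
    """
    front = store.get_front(fid)
    if front.is_retracted():
        raise UsageError(f"front {fid} is already retracted")
    unlink_child(store, front)
    i = store._i[fid.row]
    i[fid.index, _I_FLAGS] |= FLAG_RETRACTED
    i[fid.index, _I_FLAGS] &= ~(FLAG_ACTIVE | FLAG_GROWING | FLAG_MIGRATING)
    i[fid.index, _I_DEATH] = cycle
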