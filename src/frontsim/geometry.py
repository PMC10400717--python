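"""Pure 3D geometry: capsule distances, cone sampling, taper.

All coordinates are in micrometres.  Fronts are capsules: a line segment
(the central axis of a neurite cylinder) plus a radius; spherical somata are
degenerate capsules with a zero-length axis.  The minimum distance between
two capsules is the segment-segment distance minus the radii, so the single
primitive everything rests on is the closest distance between two closed 3D
line segments.
"""

from __future__ import annotations

import math

import numpy as np

from .errors import SamplingError, UsageError

_EPS = 1e-12


def _point_segment_distance_sq(p, s0, d, dd):
    """Squared distance from point p to segment s0 + t*d, t in [0,1];
    dd = d.d (may be 0 for a degenerate segment)."""
    w = (p[0] - s0[0], p[1] - s0[1], p[2] - s0[2])
    if dd < _EPS:
        return w[0] * w[0] + w[1] * w[1] + w[2] * w[2]
    t = (w[0] * d[0] + w[1] * d[1] + w[2] * d[2]) / dd
    if t < 0.0:
        t = 0.0
    elif t > 1.0:
        t = 1.0
    x = w[0] - t * d[0]
    y = w[1] - t * d[1]
    z = w[2] - t * d[2]
    return x * x + y * y + z * z


def segment_segment_distance(p0, p1, q0, q1) -> float:
    """Minimum Euclidean distance between closed segments [p0,p1] and [q0,q1].

    Degenerate (zero-length) segments are treated as points.  The computation
    follows the classic closest-point parameterisation for two segments
    (clamping the unconstrained line-line minimiser to the unit square),
    written out in plain scalar arithmetic because it sits on the hot path of
    collision detection.
    """
    u = (p1[0] - p0[0], p1[1] - p0[1], p1[2] - p0[2])
    v = (q1[0] - q0[0], q1[1] - q0[1], q1[2] - q0[2])
    a = u[0] * u[0] + u[1] * u[1] + u[2] * u[2]
    c = v[0] * v[0] + v[1] * v[1] + v[2] * v[2]
    if a < _EPS and c < _EPS:
        x = p0[0] - q0[0]
        y = p0[1] - q0[1]
        z = p0[2] - q0[2]
        return math.sqrt(x * x + y * y + z * z)
    if a < _EPS:
        return math.sqrt(_point_segment_distance_sq(p0, q0, v, c))
    if c < _EPS:
        return math.sqrt(_point_segment_distance_sq(q0, p0, u, a))

    w = (p0[0] - q0[0], p0[1] - q0[1], p0[2] - q0[2])
    b = u[0] * v[0] + u[1] * v[1] + u[2] * v[2]
    d = u[0] * w[0] + u[1] * w[1] + u[2] * w[2]
    e = v[0] * w[0] + v[1] * w[1] + v[2] * w[2]
    D = a * c - b * b
    sN, sD = D, D
    tN, tD = D, D

    if D < _EPS * a * c:
        # near-parallel: pick s = 0 edge
        sN, sD = 0.0, 1.0
        tN, tD = e, c
    else:
        sN = b * e - c * d
        tN = a * e - b * d
        if sN < 0.0:
            sN = 0.0
            tN, tD = e, c
        elif sN > sD:
            sN = sD
            tN, tD = e + b, c

    if tN < 0.0:
        tN = 0.0
        if -d < 0.0:
            sN = 0.0
        elif -d > a:
            sN = sD
        else:
            sN, sD = -d, a
    elif tN > tD:
        tN = tD
        nd = -d + b
        if nd < 0.0:
            sN = 0.0
        elif nd > a:
            sN = sD
        else:
            sN, sD = nd, a

    sc = 0.0 if abs(sN) < _EPS else sN / sD
    tc = 0.0 if abs(tN) < _EPS else tN / tD
    x = w[0] + sc * u[0] - tc * v[0]
    y = w[1] + sc * u[1] - tc * v[1]
    z = w[2] + sc * u[2] - tc * v[2]
    return math.sqrt(x * x + y * y + z * z)


def segment_distance_batch(p0, p1, q0s, q1s):
    """Distances from one segment [p0,p1] to many segments [q0s[i], q1s[i]].

    Vectorised counterpart of :func:`segment_segment_distance`; used by the
    brute-force collision sweeps that audit the grid index.  Returns an array
    of shape (n,).
    """
    p0 = np.asarray(p0, dtype=float)
    p1 = np.asarray(p1, dtype=float)
    q0s = np.asarray(q0s, dtype=float).reshape(-1, 3)
    q1s = np.asarray(q1s, dtype=float).reshape(-1, 3)

    u = p1 - p0
    v = q1s - q0s
    w = p0 - q0s
    a = float(u @ u)
    b = v @ u
    c = np.einsum("ij,ij->i", v, v)
    d = w @ u
    e = np.einsum("ij,ij->i", v, w)
    D = a * c - b * b

    # unconstrained minimisers, clamped below; guard zero denominators
    safe_D = np.where(D > _EPS * np.maximum(a * c, 1.0), D, 1.0)
    para = D <= _EPS * np.maximum(a * c, 1.0)

    sN = np.where(para, 0.0, b * e - c * d)
    sD = np.where(para, 1.0, safe_D)
    tN = np.where(para, e, a * e - b * d)
    tD = np.where(para, np.where(c > _EPS, c, 1.0), safe_D)

    # clamp s to [0,1]
    low = sN < 0.0
    sN = np.where(low, 0.0, sN)
    tN = np.where(low, e, tN)
    tD = np.where(low, np.where(c > _EPS, c, 1.0), tD)
    high = sN > sD
    sN = np.where(high, sD, sN)
    tN = np.where(high, e + b, tN)
    tD = np.where(high, np.where(c > _EPS, c, 1.0), tD)

    # clamp t to [0,1], re-minimising s on the clamped edge
    tlow = tN < 0.0
    tN = np.where(tlow, 0.0, tN)
    s_edge = np.clip(-d / a if a > _EPS else 0.0, 0.0, 1.0)
    sc0 = np.where(np.abs(sN) < _EPS, 0.0, sN / np.where(sD == 0, 1.0, sD))
    sc = np.where(tlow, s_edge, sc0)
    thigh = tN > tD
    tN = np.where(thigh, tD, tN)
    if a > _EPS:
        s_edge2 = np.clip((-d + b) / a, 0.0, 1.0)
    else:
        s_edge2 = np.zeros_like(b)
    sc = np.where(thigh, s_edge2, sc)

    tc = np.where(np.abs(tN) < _EPS, 0.0, tN / np.where(tD == 0, 1.0, tD))
    tc = np.clip(tc, 0.0, 1.0)
    sc = np.clip(sc, 0.0, 1.0)

    # degenerate target segments reduce to point-vs-segment
    degen = c < _EPS
    if np.any(degen):
        tc = np.where(degen, 0.0, tc)
        if a > _EPS:
            sc = np.where(degen, np.clip(-d / a, 0.0, 1.0), sc)
        else:
            sc = np.where(degen, 0.0, sc)

    diff = w + sc[:, None] * u[None, :] - tc[:, None] * v
    return np.sqrt(np.einsum("ij,ij->i", diff, diff))


def _orthonormal_frame(heading):
    """Two unit vectors orthogonal to `heading` and to each other."""
    h = np.asarray(heading, dtype=float)
    # pick the axis least aligned with h to avoid degeneracy
    ax = np.zeros(3)
    ax[int(np.argmin(np.abs(h)))] = 1.0
    e1 = np.cross(h, ax)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(h, e1)
    return e1, e2


def unit_heading_sample(heading, max_angle, rng, n=None):
    """Random unit vector(s) within `max_angle` degrees of `heading`.

    Directions are uniform in solid angle on the spherical cap: cos(theta) is
    drawn uniformly on [cos(max_angle), 1] and the azimuth uniformly on
    [0, 2*pi).  max_angle = 0 returns the heading itself; max_angle = 180
    gives the uniform sphere.
    """
    if not 0.0 <= max_angle <= 180.0:
        raise UsageError("max_angle must be in [0, 180] degrees")
    h = np.asarray(heading, dtype=float)
    norm = np.linalg.norm(h)
    if norm < _EPS:
        raise UsageError("heading must be a non-zero vector")
    h = h / norm
    m = 1 if n is None else int(n)
    if max_angle == 0.0:
        out = np.tile(h, (m, 1))
        return out[0] if n is None else out
    cos_max = math.cos(math.radians(max_angle))
    cos_t = rng.uniform(cos_max, 1.0, size=m)
    sin_t = np.sqrt(np.maximum(0.0, 1.0 - cos_t * cos_t))
    phi = rng.uniform(0.0, 2.0 * math.pi, size=m)
    e1, e2 = _orthonormal_frame(h)
    out = (
        cos_t[:, None] * h[None, :]
        + (sin_t * np.cos(phi))[:, None] * e1[None, :]
        + (sin_t * np.sin(phi))[:, None] * e2[None, :]
    )
    out /= np.linalg.norm(out, axis=1, keepdims=True)
    return out[0] if n is None else out


def random_unit_vector(rng, n=None):
    """Unit vector(s) uniform on the sphere."""
    m = 1 if n is None else int(n)
    v = rng.normal(size=(m, 3))
    # regenerate the (measure-zero) zero draws
    norms = np.linalg.norm(v, axis=1)
    while np.any(norms < _EPS):
        bad = norms < _EPS
        v[bad] = rng.normal(size=(int(bad.sum()), 3))
        norms = np.linalg.norm(v, axis=1)
    v /= norms[:, None]
    return v[0] if n is None else v


def unit_branching_sample(n, rng, min_separation=None, max_tries=None):
    """`n` random unit directions with pairwise angular separation.

    Used to propose candidate growth directions around a soma or a branch
    point.  Directions are uniform on the sphere, accepted one by one only if
    at least `min_separation` degrees (default 180/n) away from every
    previously accepted direction; this keeps candidates well spread so that
    several of them usually survive collision testing.

    Raises SamplingError if the constraint cannot be met within the retry
    budget (infeasible (n, min_separation) combinations).
    """
    n = int(n)
    if n < 1:
        raise UsageError("n must be >= 1")
    if min_separation is None:
        min_separation = 180.0 / n
    cos_sep = math.cos(math.radians(min_separation))
    if max_tries is None:
        max_tries = 200 * n
    accepted = []
    tries = 0
    while len(accepted) < n:
        if tries >= max_tries:
            raise SamplingError(
                f"could not draw {n} directions separated by "
                f"{min_separation:.1f} degrees in {max_tries} tries"
            )
        tries += 1
        v = random_unit_vector(rng)
        if all(float(v @ a) <= cos_sep + 1e-12 for a in accepted):
            accepted.append(v)
    return accepted


def taper(parent_radius, factor=0.9):
    """Radius of a child front relative to its parent: parent_radius * factor.

    Repeated application with factor < 1 gives the gradual thinning of
    dendrites toward their tips.
    """
    if parent_radius <= 0.0:
        raise UsageError("parent_radius must be positive")
    if not 0.0 < factor <= 1.0:
        raise UsageError("taper factor must be in (0, 1]")
    return parent_radius * factor
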