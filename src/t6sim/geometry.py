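"""Geometric primitives for spherocylinder (capsule) cells.

Capsules are parameterized by the *cylindrical segment length* ``l`` (the
distance between the two hemispherical cap centers) and radius ``r``; total
end-to-end length is ``l + 2r``.  All distances are in micrometres.
"""
from __future__ import annotations

import numpy as np

__all__ = [
    "capsule_volume",
    "cyl_length_for_volume",
    "capsule_projected_area",
    "capsule_wall_area",
    "capsule_cap_area",
    "segment_segment_distance",
    "grid_candidate_pairs",
    "grid_candidate_query",
]

_EPS = 1e-12


def capsule_volume(length, radius):
    """Volume of a capsule: cylinder plus two hemispherical caps."""
    length = np.asarray(length, dtype=float)
    radius = np.asarray(radius, dtype=float)
    return np.pi * radius**2 * length + (4.0 / 3.0) * np.pi * radius**3


def cyl_length_for_volume(volume, radius):
    """Cylindrical segment length of a capsule of given volume and radius."""
    volume = np.asarray(volume, dtype=float)
    radius = np.asarray(radius, dtype=float)
    return (volume - (4.0 / 3.0) * np.pi * radius**3) / (np.pi * radius**2)


def capsule_projected_area(length, radius):
    """Area of the capsule's in-plane projection (rectangle plus disc)."""
    return 2.0 * np.asarray(radius, float) * np.asarray(length, float) + np.pi * np.asarray(radius, float) ** 2


def capsule_wall_area(length, radius):
    return 2.0 * np.pi * np.asarray(radius, float) * np.asarray(length, float)


def capsule_cap_area(radius):
    # the two hemispherical caps together form a full sphere
    return 4.0 * np.pi * np.asarray(radius, float) ** 2


def segment_segment_distance(p1, q1, p2, q2):
    """Closest distance between line segments ``[p1,q1]`` and ``[p2,q2]``.

    Vectorized over leading dimensions. Returns ``(dist, s, t, c1, c2)``
    where ``c1 = p1 + s*(q1-p1)`` and ``c2 = p2 + t*(q2-p2)`` are the
    closest points and ``s, t`` lie in ``[0, 1]``.

    Uses the standard clamped closed-form solution (robust to degenerate,
    near-parallel and point-like segments).
    """
    p1 = np.asarray(p1, dtype=float)
    q1 = np.asarray(q1, dtype=float)
    p2 = np.asarray(p2, dtype=float)
    q2 = np.asarray(q2, dtype=float)

    d1 = q1 - p1
    d2 = q2 - p2
    r = p1 - p2
    a = np.einsum("...i,...i->...", d1, d1)
    e = np.einsum("...i,...i->...", d2, d2)
    f = np.einsum("...i,...i->...", d2, r)
    c = np.einsum("...i,...i->...", d1, r)
    b = np.einsum("...i,...i->...", d1, d2)

    a_ok = a > _EPS
    e_ok = e > _EPS
    a_safe = np.where(a_ok, a, 1.0)
    e_safe = np.where(e_ok, e, 1.0)

    denom = a * e - b * b
    denom_ok = denom > _EPS
    denom_safe = np.where(denom_ok, denom, 1.0)

    # general case: closest point of infinite lines, clamped to segment 1
    s = np.where(denom_ok, np.clip((b * f - c * e) / denom_safe, 0.0, 1.0), 0.0)
    t = (b * s + f) / e_safe
    # clamp t, then recompute (and clamp) s for the clamped t
    t_cl = np.clip(t, 0.0, 1.0)
    recompute = t != t_cl
    s_re = np.clip((t_cl * b - c) / a_safe, 0.0, 1.0)
    s = np.where(recompute, s_re, s)
    t = t_cl

    # degenerate segments
    s = np.where(a_ok, s, 0.0)
    t = np.where(e_ok, t, 0.0)
    t = np.where(a_ok | ~e_ok, t, np.clip(f / e_safe, 0.0, 1.0))

    c1 = p1 + s[..., None] * d1
    c2 = p2 + t[..., None] * d2
    diff = c1 - c2
    dist = np.sqrt(np.einsum("...i,...i->...", diff, diff))
    return dist, s, t, c1, c2


# ---------------------------------------------------------------------------
# Uniform-grid spatial hashing
# ---------------------------------------------------------------------------

_B = 1 << 19  # coordinate offset; bins live in [-_B, _B)
_STRIDE = 1 << 20


def _pack_bins(ib):
    """Pack integer bin coordinates (n, 3) into scalar int64 keys."""
    ix, iy, iz = ib[:, 0] + _B, ib[:, 1] + _B, ib[:, 2] + _B
    return (ix * _STRIDE + iy) * _STRIDE + iz


def _pack_delta(d):
    return (d[0] * _STRIDE + d[1]) * _STRIDE + d[2]


def _concat_ranges(counts):
    """[3, 0, 2] -> [0, 1, 2, 0, 1]."""
    total = int(counts.sum())
    if total == 0:
        return np.empty(0, dtype=np.int64)
    starts = np.cumsum(counts) - counts
    return np.arange(total, dtype=np.int64) - np.repeat(starts, counts)

def _neighbor_deltas(dims):
    rng = (-1, 0, 1)
    if dims == 2:
        return [(dx, dy, 0) for dx in rng for dy in rng]
    return [(dx, dy, dz) for dx in rng for dy in rng for dz in rng]


def _grid_lookup(query_keys, sorted_keys, order, deltas):
    qi_all, cj_all = [], []
    nq = len(query_keys)
    for d in deltas:
        target = query_keys + _pack_delta(d)
        left = np.searchsorted(sorted_keys, target, side="left")
        right = np.searchsorted(sorted_keys, target, side="right")
        cnt = right - left
        if cnt.sum() == 0:
            continue
        qi = np.repeat(np.arange(nq, dtype=np.int64), cnt)
        pos = np.repeat(left, cnt) + _concat_ranges(cnt)
        qi_all.append(qi)
        cj_all.append(order[pos])
    if not qi_all:
        return np.empty(0, np.int64), np.empty(0, np.int64)
    return np.concatenate(qi_all), np.concatenate(cj_all)


def grid_candidate_pairs(points, bin_size, dims=3):
    """Candidate interaction pairs ``(i, j)`` with ``i < j`` from a uniform grid.

    Complete for objects whose interaction radius (sum of half-extents plus
    threshold, measured between the two ``points``) does not exceed
    ``bin_size``.
    """
    points = np.asarray(points, dtype=float)
    n = len(points)
    if n < 2:
        return np.empty(0, np.int64), np.empty(0, np.int64)
    ib = np.floor(points / bin_size).astype(np.int64)
    keys = _pack_bins(ib)
    order = np.argsort(keys, kind="stable")
    sorted_keys = keys[order]
    qi, cj = _grid_lookup(keys, sorted_keys, order, _neighbor_deltas(dims))
    mask = qi < cj
    return qi[mask], cj[mask]


def grid_candidate_query(query_points, points, bin_size, dims=3):
    """Candidate pairs ``(query_index, point_index)`` from a uniform grid."""
    query_points = np.asarray(query_points, dtype=float)
    points = np.asarray(points, dtype=float)
    if len(query_points) == 0 or len(points) == 0:
        return np.empty(0, np.int64), np.empty(0, np.int64)
    ib = np.floor(points / bin_size).astype(np.int64)
    keys = _pack_bins(ib)
    order = np.argsort(keys, kind="stable")
    sorted_keys = keys[order]
    qb = np.floor(query_points / bin_size).astype(np.int64)
    qkeys = _pack_bins(qb)
    return _grid_lookup(qkeys, sorted_keys, order, _neighbor_deltas(dims))


def perpendicular_basis(axes):
    """Two unit vectors orthogonal to each row of ``axes`` (n, 3)."""
    axes = np.asarray(axes, dtype=float)
    # choose the world axis least aligned with each cell axis
    ref = np.zeros_like(axes)
    ref[np.arange(len(axes)), np.argmin(np.abs(axes), axis=1)] = 1.0
    e1 = np.cross(axes, ref)
    e1 /= np.linalg.norm(e1, axis=1, keepdims=True)
    e2 = np.cross(axes, e1)
    e2 /= np.linalg.norm(e2, axis=1, keepdims=True)
    return e1, e2
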