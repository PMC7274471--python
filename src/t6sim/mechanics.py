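"""Capsule overlap detection and quasistatic mechanical relaxation.

Overlaps between capsules are found with a uniform-grid broad phase and an
exact segment-segment narrow phase.  Relaxation solves the regularized
normal system ``(J^T J + alpha*M) p = J^T d`` for per-cell impulses ``p``
(translations plus small rotations), where each row of the contact Jacobian
``J`` maps impulses to gap opening at one contact and ``d`` holds the
penetration depths.  The solve uses conjugate gradients; newly created
overlaps are re-resolved by repeating detect/solve/apply.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
from scipy.sparse.linalg import cg

from .cells import CellState, Population
from .geometry import (
    grid_candidate_pairs,
    perpendicular_basis,
    segment_segment_distance,
)

__all__ = ["ContactGraph", "MechanicsParams", "Plane", "detect_contacts", "relax"]


@dataclass
class MechanicsParams:
    contact_threshold: float = 0.01  # um; surfaces closer than this "touch"
    alpha: float = 1.0               # regularization weight on movement cost
    cg_tolerance: float = 1e-3       # absolute CG tolerance, um
    max_resolution_iters: int = 10   # detect/solve/apply repetitions
    cg_maxiter: int = 300

    def __post_init__(self):
        if self.contact_threshold <= 0 or self.alpha <= 0 or self.cg_tolerance <= 0:
            raise ValueError("contact_threshold, alpha and cg_tolerance must be > 0")
        if self.max_resolution_iters < 1:
            raise ValueError("max_resolution_iters must be >= 1")


@dataclass
class Plane:
    """A unilateral wall; ``normal`` points into the allowed half-space."""

    point: np.ndarray
    normal: np.ndarray

    def __post_init__(self):
        self.point = np.asarray(self.point, dtype=float)
        n = np.asarray(self.normal, dtype=float)
        self.normal = n / np.linalg.norm(n)


@dataclass
class ContactGraph:
    """Pairwise near-contacts: ``gap`` is the signed surface separation
    (negative = interpenetration); pairs with ``gap <= threshold`` are kept.
    """

    i: np.ndarray
    j: np.ndarray
    gap: np.ndarray
    point: np.ndarray    # (m, 3) midpoint between closest surface points
    normal: np.ndarray   # (m, 3) unit, pointing from cell i toward cell j
    built_at: float = 0.0
    threshold: float = 0.01

    @property
    def n_pairs(self) -> int:
        return len(self.i)

    def degree(self, n_cells: int) -> np.ndarray:
        """Number of touching partners per cell."""
        deg = np.zeros(n_cells, dtype=np.int64)
        np.add.at(deg, self.i, 1)
        np.add.at(deg, self.j, 1)
        return deg


def _pair_geometry(pop: Population, ci, cj):
    pa, pb = pop.endpoints()
    dist, s, t, c1, c2 = segment_segment_distance(pa[ci], pb[ci], pa[cj], pb[cj])
    gap = dist - (pop.radius[ci] + pop.radius[cj])
    diff = c2 - c1
    with np.errstate(invalid="ignore", divide="ignore"):
        normal = np.where(dist[:, None] > 1e-12, diff / np.maximum(dist, 1e-12)[:, None], 0.0)
    # coincident axes: fall back to an arbitrary perpendicular direction
    degen = dist <= 1e-12
    if degen.any():
        e1, _ = perpendicular_basis(pop.axis[ci][degen])
        normal[degen] = e1
    point = 0.5 * (c1 + c2)
    return gap, point, normal


def detect_contacts(pop: Population, threshold: float = 0.01,
                    brute_force: bool = False) -> ContactGraph:
    """All capsule pairs whose surface separation is at most ``threshold``.

    REMOVED cells never appear (the engine compacts them away, but any
    present rows are skipped); VICTIM corpses are solid and included.
    """
    active = pop.state != int(CellState.REMOVED)
    idx = np.flatnonzero(active)
    if len(idx) < 2:
        return ContactGraph(np.empty(0, np.int64), np.empty(0, np.int64),
                            np.empty(0), np.empty((0, 3)), np.empty((0, 3)),
                            built_at=pop.clock.t, threshold=threshold)
    if brute_force:
        ii, jj = np.triu_indices(len(idx), k=1)
        ci, cj = idx[ii], idx[jj]
    else:
        bin_size = float(2.0 * pop.half_extent[idx].max() + threshold + 0.5)
        qi, qj = grid_candidate_pairs(pop.center[idx], bin_size)
        ci, cj = idx[qi], idx[qj]
    gap, point, normal = _pair_geometry(pop, ci, cj)
    keep = gap <= threshold
    return ContactGraph(ci[keep], cj[keep], gap[keep], point[keep], normal[keep],
                        built_at=pop.clock.t, threshold=threshold)


def _wall_contacts(pop: Population, walls, threshold):
    """Unilateral endpoint-sphere / plane contacts: (cell, depth, point, normal)."""
    rows_i, depth, points, normals = [], [], [], []
    pa, pb = pop.endpoints()
    active = pop.state != int(CellState.REMOVED)
    for plane in walls:
        for pts in (pa, pb):
            d = (pts - plane.point) @ plane.normal  # signed distance of cap center
            pen = pop.radius - d                     # > 0: sphere through wall
            m = active & (pen > -threshold)
            if not m.any():
                continue
            rows_i.append(np.flatnonzero(m))
            depth.append(pen[m])
            points.append(pts[m] - d[m, None] * plane.normal[None, :])
            normals.append(np.broadcast_to(plane.normal, (int(m.sum()), 3)).copy())
    if not rows_i:
        return (np.empty(0, np.int64), np.empty(0), np.empty((0, 3)), np.empty((0, 3)))
    return (np.concatenate(rows_i), np.concatenate(depth),
            np.vstack(points), np.vstack(normals))


def _build_system(pop: Population, contacts: ContactGraph, wall_rows, dims: int,
                  params: MechanicsParams):
    """Sparse Jacobian J (constraints x dofs), target d, and regularizer M."""
    n = pop.n
    ndof_cell = 3 if dims == 2 else 5
    pen_mask = contacts.gap < 0.0
    ci, cj = contacts.i[pen_mask], contacts.j[pen_mask]
    pts, nrm = contacts.point[pen_mask], contacts.normal[pen_mask]
    d_pairs = -contacts.gap[pen_mask]

    wi, wdepth, wpts, wnrm = wall_rows
    wpen = wdepth > 0.0
    wi, wdepth, wpts, wnrm = wi[wpen], wdepth[wpen], wpts[wpen], wnrm[wpen]

    m_pairs, m_walls = len(ci), len(wi)
    m = m_pairs + m_walls
    if m == 0:
        return None, None, None

    rows, cols, vals = [], [], []

    if dims == 3:
        e1, e2 = perpendicular_basis(pop.axis)

    def add_body(row_idx, cells, normals, points, sign):
        """Jacobian block for one body of each contact; gap opens along
        +normal motion of the body when sign=+1."""
        r = points - pop.center[cells]
        base = cells * ndof_cell
        for k in range(3 if dims == 3 else 2):
            rows.append(row_idx)
            cols.append(base + k)
            vals.append(sign * normals[:, k])
        if dims == 2:
            # rotation about z: point velocity = theta * (z x r)
            zxr = np.stack([-r[:, 1], r[:, 0]], axis=1)
            rows.append(row_idx)
            cols.append(base + 2)
            vals.append(sign * np.einsum("ij,ij->i", zxr, normals[:, :2]))
        else:
            for k, ek in enumerate((e1, e2)):
                exr = np.cross(ek[cells], r)
                rows.append(row_idx)
                cols.append(base + 3 + k)
                vals.append(sign * np.einsum("ij,ij->i", exr, normals))

    if m_pairs:
        ridx = np.arange(m_pairs, dtype=np.int64)
        add_body(ridx, cj, nrm, pts, +1.0)   # j moves along +n to open gap
        add_body(ridx, ci, nrm, pts, -1.0)
    if m_walls:
        ridx = m_pairs + np.arange(m_walls, dtype=np.int64)
        add_body(ridx, wi, wnrm, wpts, +1.0)  # wall normal points inward

    J = sp.coo_matrix(
        (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
        shape=(m, n * ndof_cell),
    ).tocsr()
    d = np.concatenate([d_pairs, wdepth])
    # movement-cost regularizer: identity scaled by cell total length
    total_len = pop.length + 2.0 * pop.radius
    M = sp.diags(np.repeat(total_len, ndof_cell))
    return J, d, M


def _apply_impulses(pop: Population, p: np.ndarray, dims: int):
    ndof_cell = 3 if dims == 2 else 5
    p = p.reshape(pop.n, ndof_cell)
    if dims == 2:
        pop.center[:, 0] += p[:, 0]
        pop.center[:, 1] += p[:, 1]
        theta = p[:, 2]
        cos, sin = np.cos(theta), np.sin(theta)
        ax, ay = pop.axis[:, 0].copy(), pop.axis[:, 1].copy()
        pop.axis[:, 0] = cos * ax - sin * ay
        pop.axis[:, 1] = sin * ax + cos * ay
        trans = np.linalg.norm(p[:, :2], axis=1)
    else:
        pop.center += p[:, :3]
        e1, e2 = perpendicular_basis(pop.axis)
        pop.axis += p[:, 3:4] * np.cross(e1, pop.axis) + p[:, 4:5] * np.cross(e2, pop.axis)
        pop.axis /= np.linalg.norm(pop.axis, axis=1, keepdims=True)
        trans = np.linalg.norm(p[:, :3], axis=1)
    return trans


def residual_load(pop: Population, contacts: ContactGraph | None = None,
                  walls: list[Plane] | None = None,
                  threshold: float = 0.01) -> np.ndarray:
    """Per-cell summed unresolved penetration depth (um).

    This is the "pressure" signal consumed by
    :func:`t6sim.growth.mechanical_restriction`: it vanishes for unloaded
    cells and grows with the compression a jammed cell sustains (a
    displacement-based signal would read zero exactly when a cell is
    wedged and cannot move).
    """
    if contacts is None:
        contacts = detect_contacts(pop, threshold)
    load = np.zeros(pop.n)
    pen = np.maximum(0.0, -contacts.gap)
    np.add.at(load, contacts.i, pen)
    np.add.at(load, contacts.j, pen)
    if walls:
        wi, wdepth, _, _ = _wall_contacts(pop, walls, threshold)
        np.add.at(load, wi, np.maximum(0.0, wdepth))
    return load


def relax(pop: Population, params: MechanicsParams | None = None,
          walls: list[Plane] | None = None, dims: int = 2,
          return_impulses: bool = False) -> np.ndarray:
    """Restore quasistatic mechanical equilibrium in place.

    Returns the per-cell residual contact load (see :func:`residual_load`)
    used as the crowding-pressure input to growth restriction, or -- with
    ``return_impulses`` -- the per-cell summed impulse magnitude (um)
    accumulated over the resolution iterations.
    """
    if params is None:
        params = MechanicsParams()
    walls = walls or []
    impulses = np.zeros(pop.n)
    if pop.n == 0:
        return impulses
    for _ in range(params.max_resolution_iters):
        contacts = detect_contacts(pop, params.contact_threshold)
        wall_rows = _wall_contacts(pop, walls, params.contact_threshold)
        system = _build_system(pop, contacts, wall_rows, dims, params)
        if system[0] is None:
            break
        J, d, M = system
        if d.max() <= params.contact_threshold:
            break  # residual interpenetration already below the touch scale
        A = (J.T @ J + params.alpha * M).tocsr()
        rhs = J.T @ d
        p, info = cg(A, rhs, rtol=0.0, atol=params.cg_tolerance,
                     maxiter=params.cg_maxiter)
        if info > 0:
            warnings.warn("conjugate gradients did not converge; using best iterate",
                          RuntimeWarning, stacklevel=2)
        impulses += _apply_impulses(pop, p, dims)
    else:
        contacts = detect_contacts(pop, params.contact_threshold)
        if contacts.n_pairs and (contacts.gap < -params.contact_threshold).any():
            warnings.warn(
                "max_resolution_iters reached with residual overlaps",
                RuntimeWarning, stacklevel=2)
    pop.check_finite()
    if return_impulses:
        return impulses
    return residual_load(pop, walls=walls, threshold=params.contact_threshold)
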