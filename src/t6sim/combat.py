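"""Discrete T6SS firing, needle geometry, hit resolution and intoxication.

Each timestep, every attacker draws a Poisson number of firings with mean
``k_fire * dt`` and pays a growth-cost multiplier ``1 - c*N/dt`` (floored
at 0).  A needle is a segment of length ``L_needle = R`` anchored at a
uniformly area-sampled surface point, pointing along the outward normal.
A needle strikes the nearest cell (other than its firer) whose axis
segment comes within that cell's radius of the needle segment; corpses
(VICTIM cells) absorb needles.  Hits are tallied per attacking genotype;
same-genotype tallies are recorded but never lethal (self-immunity).  When
any non-kin tally reaches the target's ``N_hits``, the target becomes a
VICTIM and is removed after a lysis delay ``1/k_lysis`` of the genotype
that delivered the lethal hit.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .cells import Cell, CellState, Event, Population
from .geometry import (
    capsule_cap_area,
    capsule_wall_area,
    grid_candidate_query,
    perpendicular_basis,
    segment_segment_distance,
)

__all__ = [
    "CombatParams",
    "Needle",
    "sample_firings",
    "firing_cost",
    "construct_needle",
    "construct_needles",
    "resolve_hits",
    "apply_intoxication",
    "advance_lysis",
]


@dataclass
class CombatParams:
    deterministic_lysis: bool = True  # exact 1/k_lysis delay; else exponential


@dataclass
class Needle:
    origin: np.ndarray       # point on the firer's surface
    direction: np.ndarray    # outward unit normal at the origin
    length: float            # = firer radius
    firer_id: int
    firer_genotype_id: int


def sample_firings(k_fire: float, dt: float, rng: np.random.Generator,
                   n: int | None = None):
    """Poisson draw(s) of firing counts with per-step mean ``k_fire * dt``."""
    if k_fire < 0:
        raise ValueError("k_fire must be >= 0")
    if dt <= 0:
        raise ValueError("dt must be > 0")
    return rng.poisson(k_fire * dt, size=n)


def firing_cost(n_firings, dt: float, c: float):
    """Growth multiplier ``1 - c * (N_firings / dt)``, floored at 0."""
    if dt <= 0:
        raise ValueError("dt must be > 0")
    return np.maximum(0.0, 1.0 - c * (np.asarray(n_firings, dtype=float) / dt))


def _sample_surface(centers, axes, lengths, radii, rng):
    """Uniform-by-area points and outward normals on capsule surfaces.

    All arguments are per-needle arrays (one row per needle to construct).
    Returns (origins, normals).
    """
    n = len(centers)
    wall = capsule_wall_area(lengths, radii)
    cap = capsule_cap_area(radii)
    on_wall = rng.uniform(size=n) < wall / (wall + cap)
    e1, e2 = perpendicular_basis(axes)
    origins = np.empty((n, 3))
    normals = np.empty((n, 3))

    # cylindrical wall: uniform along axis, uniform azimuth
    if on_wall.any():
        m = on_wall
        u = rng.uniform(-0.5, 0.5, size=int(m.sum())) * lengths[m]
        phi = rng.uniform(0.0, 2.0 * np.pi, size=int(m.sum()))
        nrm = np.cos(phi)[:, None] * e1[m] + np.sin(phi)[:, None] * e2[m]
        origins[m] = centers[m] + u[:, None] * axes[m] + radii[m, None] * nrm
        normals[m] = nrm
    # hemispherical caps: uniform on the sphere, assigned to the matching cap
    if (~on_wall).any():
        m = ~on_wall
        k = int(m.sum())
        v = rng.normal(size=(k, 3))
        v /= np.linalg.norm(v, axis=1, keepdims=True)
        side = np.sign(np.einsum("ij,ij->i", v, axes[m]))
        side[side == 0] = 1.0
        tips = centers[m] + (side * 0.5 * lengths[m])[:, None] * axes[m]
        origins[m] = tips + radii[m, None] * v
        normals[m] = v
    return origins, normals


def construct_needle(cell: Cell, rng: np.random.Generator) -> Needle:
    """Build one needle from an ALIVE attacker cell."""
    if cell.state != CellState.ALIVE:
        raise ValueError("only ALIVE cells fire")
    origins, normals = _sample_surface(
        cell.center[None, :], cell.axis[None, :],
        np.array([cell.length]), np.array([cell.radius]), rng)
    return Needle(origin=origins[0], direction=normals[0], length=cell.radius,
                  firer_id=cell.id, firer_genotype_id=cell.genotype_id)


def construct_needles(pop: Population, firer_idx: np.ndarray,
                      rng: np.random.Generator):
    """Vectorized needle construction; ``firer_idx`` has one entry per needle."""
    origins, normals = _sample_surface(
        pop.center[firer_idx], pop.axis[firer_idx],
        pop.length[firer_idx], pop.radius[firer_idx], rng)
    lengths = pop.radius[firer_idx]
    return origins, normals, lengths


def resolve_hits(pop: Population, origins: np.ndarray, directions: np.ndarray,
                 lengths: np.ndarray, firer_idx: np.ndarray,
                 brute_force: bool = False) -> np.ndarray:
    """Struck cell row index per needle (-1 for a miss).

    A candidate target is any non-REMOVED cell (VICTIM corpses absorb
    needles) other than the firer whose axis segment passes within the
    target's radius of the needle segment; among several candidates the one
    intersected nearest the needle origin wins.
    """
    n_needles = len(origins)
    struck = np.full(n_needles, -1, dtype=np.int64)
    if n_needles == 0 or pop.n == 0:
        return struck
    active = pop.state != int(CellState.REMOVED)
    idx = np.flatnonzero(active)
    if brute_force:
        qi = np.repeat(np.arange(n_needles), len(idx))
        cj = np.tile(idx, n_needles)
    else:
        bin_size = float(2.0 * pop.half_extent[idx].max() + lengths.max() + 0.5)
        qi, lo = grid_candidate_query(origins, pop.center[idx], bin_size)
        cj = idx[lo]
    if len(qi) == 0:
        return struck
    not_self = cj != firer_idx[qi]
    qi, cj = qi[not_self], cj[not_self]
    if len(qi) == 0:
        return struck

    pa, pb = pop.endpoints()
    tips = origins + lengths[:, None] * directions
    dist, t_needle, _, _, _ = segment_segment_distance(
        origins[qi], tips[qi], pa[cj], pb[cj])
    hit = dist <= pop.radius[cj]
    qi, cj, t_needle, dist = qi[hit], cj[hit], t_needle[hit], dist[hit]
    if len(qi) == 0:
        return struck
    # nearest intersection along the needle; ties broken by distance then id
    order = np.lexsort((pop.id[cj], dist, t_needle, qi))
    qi, cj = qi[order], cj[order]
    first = np.unique(qi, return_index=True)[1]
    struck[qi[first]] = cj[first]
    return struck


def apply_intoxication(pop: Population, struck_idx: np.ndarray,
                       firer_geno_slot: np.ndarray, now: float,
                       rng: np.random.Generator,
                       params: CombatParams | None = None) -> list[Event]:
    """Record hits, apply self-immunity, and mark newly lethal cells VICTIM.

    ``struck_idx``/``firer_geno_slot`` are parallel arrays (misses already
    filtered out).  Returns HIT and DEATH events.
    """
    params = params or CombatParams()
    events: list[Event] = []
    if len(struck_idx) == 0:
        return events
    np.add.at(pop.tallies, (struck_idx, firer_geno_slot), 1)
    geno_ids = [g.id for g in pop.genotypes]
    # aux encodes the target at the moment of impact:
    # +2 if non-kin (different genotype from the firer), +1 if already dead
    nonkin = pop.genotype[struck_idx] != firer_geno_slot
    was_victim = pop.state[struck_idx] == int(CellState.VICTIM)
    for q in range(len(struck_idx)):
        events.append(Event(now, "HIT", int(pop.id[struck_idx[q]]),
                            geno_ids[firer_geno_slot[q]],
                            float(2 * nonkin[q] + was_victim[q])))

    # lethality check only for cells struck this step and still ALIVE
    cand = np.unique(struck_idx[pop.state[struck_idx] == int(CellState.ALIVE)])
    if len(cand) == 0:
        return events
    n_hits = np.array([g.lethal_hit_threshold for g in pop.genotypes])
    nonkin = pop.tallies[cand].copy()
    nonkin[np.arange(len(cand)), pop.genotype[cand]] = 0  # self-immunity
    lethal = (nonkin >= n_hits[pop.genotype[cand]][:, None]).any(axis=1)
    for row in cand[lethal]:
        over = np.flatnonzero(
            (pop.tallies[row] >= n_hits[pop.genotype[row]])
            & (np.arange(len(pop.genotypes)) != pop.genotype[row]))
        # the genotype whose hit crossed the threshold this step; with several,
        # the one delivering the earliest crossing hit in needle order
        killer_slot = int(over[0])
        if len(over) > 1:
            mask = struck_idx == row
            for slot in firer_geno_slot[mask]:
                if slot in over:
                    killer_slot = int(slot)
                    break
        killer = pop.genotypes[killer_slot]
        delay = 1.0 / killer.toxin_lysis_rate
        if not params.deterministic_lysis:
            delay = rng.exponential(delay)
        pop.state[row] = int(CellState.VICTIM)
        pop.death_time[row] = now
        pop.lysis_delay[row] = delay
        # aux carries the victim's own genotype id (kind field holds the killer's)
        events.append(Event(now, "DEATH", int(pop.id[row]), killer.id,
                            float(pop.genotypes[pop.genotype[row]].id)))
    return events


def advance_lysis(pop: Population, now: float) -> list[Event]:
    """Remove every VICTIM whose lysis delay has elapsed; returns LYSIS events."""
    due = np.flatnonzero((pop.state == int(CellState.VICTIM))
                         & (now >= pop.death_time + pop.lysis_delay - 1e-12))
    events = [Event(now, "LYSIS", int(pop.id[i]),
                    pop.genotypes[pop.genotype[i]].id) for i in due]
    if len(due):
        pop.state[due] = int(CellState.REMOVED)
    return events
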