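"""Exponential cell growth with firing costs, crowding restriction, and
lengthwise binary fission.

Growth follows ``dV_i/dt = k_grow,i * V_i`` discretized as
``dV_i = k_grow,i * V_i * dt``, modulated by the weapon-cost multiplier
(``1 - c*N_firings/dt``, floored at 0) and by a crowding multiplier that
decreases monotonically with the mechanical pressure a cell experienced in
the previous relaxation.  Cells divide into two equal-volume daughters once
their volume reaches ``2*V0 + eta`` (``eta`` uniform noise, cached at
birth), with each daughter axis perturbed by a small random rotation.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .cells import Cell, CellState, Event, Population
from .geometry import capsule_volume, cyl_length_for_volume

__all__ = [
    "GrowthParams",
    "grow",
    "grow_population",
    "mechanical_restriction",
    "maybe_divide",
    "divide_population",
    "DEFAULT_RADIUS",
    "DEFAULT_BIRTH_LENGTH",
    "DEFAULT_BIRTH_VOLUME",
]

# Nominal newborn capsule: 2 um end-to-end, 0.5 um radius
DEFAULT_RADIUS = 0.5
DEFAULT_BIRTH_LENGTH = 1.0  # cylindrical segment; total length = 2 um
DEFAULT_BIRTH_VOLUME = float(capsule_volume(DEFAULT_BIRTH_LENGTH, DEFAULT_RADIUS))


@dataclass
class GrowthParams:
    division_noise_scale: float = 0.05 * DEFAULT_BIRTH_VOLUME  # eta_division, um^3
    orientation_noise_scale: float = 0.05                      # eta_orientations, rad
    restriction_strength: float = 0.0                          # 1/gamma; 0 disables
    # pressure (um of accumulated impulse) at which crowding slowdown kicks in
    pressure_scale: float = 0.01

    def __post_init__(self):
        if min(self.division_noise_scale, self.orientation_noise_scale,
               self.restriction_strength) < 0:
            raise ValueError("growth noise scales and restriction must be >= 0")


def mechanical_restriction(cell_pressure, restriction_strength: float,
                           pressure_scale: float = 0.01):
    """Crowding growth multiplier in (0, 1].

    ``multiplier = 1 / (1 + (1/gamma) * P)`` with ``P`` the per-cell impulse
    magnitude normalized by ``pressure_scale``.  Equals 1 for unloaded cells
    or when the restriction is disabled, and decreases monotonically with
    pressure.
    """
    p = np.asarray(cell_pressure, dtype=float)
    if (p < 0).any():
        raise ValueError("pressure must be >= 0")
    return 1.0 / (1.0 + restriction_strength * p / pressure_scale)


def grow(cell: Cell, dt: float, cost_multiplier: float = 1.0,
         restriction_multiplier: float = 1.0) -> Cell:
    """Grow one ALIVE cell for ``dt`` hours; VICTIM cells never grow."""
    if dt < 0:
        raise ValueError("dt must be >= 0")
    if not (0.0 <= cost_multiplier <= 1.0) or not (0.0 < restriction_multiplier <= 1.0):
        raise ValueError("multipliers out of range")
    if cell.state != CellState.ALIVE:
        return cell
    dV = cell.growth_rate * cost_multiplier * restriction_multiplier * cell.volume * dt
    new_vol = cell.volume + dV
    cell.length = float(cyl_length_for_volume(new_vol, cell.radius))
    return cell


def grow_population(pop: Population, dt: float, cost_multiplier: np.ndarray,
                    params: GrowthParams):
    """Vectorized growth update over every ALIVE cell (in place)."""
    alive = pop.state == int(CellState.ALIVE)
    if not alive.any():
        return
    restr = mechanical_restriction(pop.pressure[alive], params.restriction_strength,
                                   params.pressure_scale)
    vol = pop.volume[alive]
    dV = pop.growth_rate[alive] * cost_multiplier[alive] * restr * vol * dt
    pop.length[alive] = cyl_length_for_volume(vol + dV, pop.radius[alive])


def _perturb_axis(axis: np.ndarray, scale: float, rng: np.random.Generator,
                  dims: int) -> np.ndarray:
    if scale == 0:
        return axis.copy()
    if dims == 2:
        theta = rng.normal(0.0, scale)
        cos, sin = np.cos(theta), np.sin(theta)
        return np.array([cos * axis[0] - sin * axis[1],
                         sin * axis[0] + cos * axis[1], axis[2]])
    # 3D: small rotation about a random axis perpendicular to the cell axis
    ref = np.zeros(3)
    ref[np.argmin(np.abs(axis))] = 1.0
    e1 = np.cross(axis, ref)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(axis, e1)
    phi = rng.uniform(0.0, 2.0 * np.pi)
    perp = np.cos(phi) * e1 + np.sin(phi) * e2
    theta = rng.normal(0.0, scale)
    new = axis + theta * np.cross(perp, axis)
    return new / np.linalg.norm(new)


def _make_daughters(pop: Population, idx: int, params: GrowthParams,
                    nominal_v0: float, rng: np.random.Generator, dims: int):
    vol = float(pop.volume[idx])
    radius = float(pop.radius[idx])
    l_d = float(cyl_length_for_volume(vol / 2.0, radius))
    if l_d <= 0:
        return None  # geometrically too short to split; grow further first
    center = pop.center[idx]
    axis = pop.axis[idx]
    # daughters sit end-to-end with a shallow axial overlap: keeps the
    # segment-segment contact normal well-defined (axial, not degenerate)
    # while relaxation opens the remaining 0.05 um
    overlap = 0.05
    offset = 0.5 * l_d + radius - 0.5 * overlap
    daughters = []
    for sign in (-1.0, 1.0):
        d_axis = _perturb_axis(axis, params.orientation_noise_scale, rng, dims)
        eta = rng.uniform(0.0, params.division_noise_scale)
        daughters.append(Cell(
            id=pop.new_cell_id(),
            genotype_id=pop.genotypes[pop.genotype[idx]].id,
            center=center + sign * offset * axis,
            axis=d_axis,
            length=l_d,
            radius=radius,
            growth_rate=float(pop.growth_rate[idx]),
            birth_volume=vol / 2.0,
            div_threshold=2.0 * nominal_v0 + eta,
        ))
    return daughters


def maybe_divide(cell: Cell, rng: np.random.Generator,
                 params: GrowthParams | None = None,
                 nominal_v0: float | None = None, dims: int = 2):
    """Divide a single cell record if it has reached its threshold.

    Returns ``[cell]`` unchanged if below the cached division threshold,
    else two equal-volume daughters placed end-to-end within the parent's
    footprint.  Daughters inherit genotype and growth rate, start with
    empty hit tallies, and draw fresh division noise.
    """
    if cell.state != CellState.ALIVE:
        return [cell]
    if cell.volume < cell.div_threshold:
        return [cell]
    params = params or GrowthParams()
    if nominal_v0 is None:
        nominal_v0 = cell.div_threshold / 2.0
    from .cells import Genotype, Population as _Pop  # local: tiny scratch pop

    geno = Genotype(id=cell.genotype_id, name="g", is_attacker=False)
    scratch = _Pop([geno])
    scratch.append_cell(cell)
    daughters = _make_daughters(scratch, 0, params, nominal_v0, rng, dims)
    return [cell] if daughters is None else daughters


def divide_population(pop: Population, params: GrowthParams, nominal_v0: float,
                      rng: np.random.Generator, dims: int = 2) -> list[Event]:
    """Divide every ALIVE cell at/above its threshold; returns DIVIDE events."""
    ready = np.flatnonzero((pop.state == int(CellState.ALIVE))
                           & (pop.volume >= pop.div_threshold))
    if len(ready) == 0:
        return []
    events = []
    keep = np.ones(pop.n, dtype=bool)
    new_cells = []
    for idx in ready:
        daughters = _make_daughters(pop, idx, params, nominal_v0, rng, dims)
        if daughters is None:
            continue
        keep[idx] = False
        new_cells.extend(daughters)
        events.append(Event(pop.clock.t, "DIVIDE", int(pop.id[idx]),
                            pop.genotypes[pop.genotype[idx]].id))
    pop.compact(keep)
    for c in new_cells:
        pop.append_cell(c)
    return events
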