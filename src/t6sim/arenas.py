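"""Simulation protocols: 2D disc competitions, 3D biofilms with sloughing,
and open-ended microfluidic chambers.

* ``disc2d`` -- a 1:1 inoculum (100 cells by default) scattered in a
  100-um-diameter circle grows as a monolayer until the living + victim
  population exceeds a cap (10,000 by default).
* ``biofilm3d`` -- one cell of each strain on the floor of a walled box
  (40 x 40 um base); cells carried above the slough height (20 um) are
  removed; runs for a fixed duration (13 h).
* ``chamber`` -- a walled 10 x 100 um channel open at both short ends;
  a central susceptible cell flanked by two rows of five attackers grows
  for a burn-in period (3 h) that defines t = 0, then competes for a fixed
  duration with cells forced past the open ends removed.
"""
from __future__ import annotations

import numpy as np

from .cells import Cell, CellState, Population, SimClock, Trajectory
from .combat import CombatParams
from .config import RunConfig, default_config
from .engine import Simulation
from .geometry import segment_segment_distance
from .growth import (
    DEFAULT_BIRTH_LENGTH,
    DEFAULT_BIRTH_VOLUME,
    DEFAULT_RADIUS,
    GrowthParams,
)
from .mechanics import MechanicsParams, Plane

__all__ = ["run_disc2d", "run_biofilm3d", "run_chamber", "run_arena"]


class InoculumError(RuntimeError):
    pass


def _growth_params(cfg: RunConfig) -> GrowthParams:
    noise = cfg.growth.division_noise_scale
    if noise is None:
        noise = 0.05 * DEFAULT_BIRTH_VOLUME
    return GrowthParams(division_noise_scale=noise,
                        orientation_noise_scale=cfg.growth.orientation_noise_scale,
                        restriction_strength=cfg.growth.restriction_strength)


def _mech_params(cfg: RunConfig) -> MechanicsParams:
    m = cfg.mechanics
    return MechanicsParams(contact_threshold=m.contact_threshold, alpha=m.alpha,
                           cg_tolerance=m.cg_tolerance,
                           max_resolution_iters=m.max_resolution_iters)


def _desync_initial_sizes(pop: Population, rng: np.random.Generator):
    """Spread inoculum cells across the cell cycle so divisions desynchronize."""
    u = rng.uniform(size=pop.n)
    vols = DEFAULT_BIRTH_VOLUME * 2.0 ** u  # exponential-age size distribution
    from .geometry import cyl_length_for_volume

    pop.length = np.asarray(cyl_length_for_volume(vols, pop.radius))


def _make_cell(pop: Population, genotype_id: int, center, axis,
               growth_rate: float) -> int:
    axis = np.asarray(axis, float)
    axis = axis / np.linalg.norm(axis)
    return pop.append_cell(Cell(
        id=pop.new_cell_id(), genotype_id=genotype_id,
        center=np.asarray(center, float), axis=axis,
        length=DEFAULT_BIRTH_LENGTH, radius=DEFAULT_RADIUS,
        growth_rate=growth_rate))


def _scatter_disc(pop: Population, cfg: RunConfig, rng: np.random.Generator):
    """Random 1:1 placement in the disc with shallow-overlap rejection."""
    radius = cfg.disc_diameter / 2.0
    n = cfg.inoculum_size
    n_att = int(round(n * cfg.attacker_fraction))
    genos = pop.genotypes
    att_id = next(g.id for g in genos if g.is_attacker) if any(
        g.is_attacker for g in genos) else genos[0].id
    sus_id = next((g.id for g in genos if not g.is_attacker), genos[-1].id)
    kinds = [att_id] * n_att + [sus_id] * (n - n_att)
    placed_centers, placed_axes = [], []
    margin = DEFAULT_BIRTH_LENGTH / 2.0 + DEFAULT_RADIUS
    if radius <= margin:
        raise InoculumError("disc too small for even one cell")
    for gid in kinds:
        for attempt in range(2000):
            r = (radius - margin) * np.sqrt(rng.uniform())
            phi = rng.uniform(0, 2 * np.pi)
            center = np.array([r * np.cos(phi), r * np.sin(phi), 0.0])
            theta = rng.uniform(0, 2 * np.pi)
            axis = np.array([np.cos(theta), np.sin(theta), 0.0])
            if _placement_ok(center, axis, placed_centers, placed_axes):
                break
        else:
            raise InoculumError(
                f"could not place {cfg.inoculum_size} cells in a "
                f"{cfg.disc_diameter}-um circle")
        placed_centers.append(center)
        placed_axes.append(axis)
        g = next(g for g in genos if g.id == gid)
        _make_cell(pop, gid, center, axis, g.base_growth_rate)


def _placement_ok(center, axis, centers, axes, min_gap=-0.3):
    """Reject placements with deep overlap; shallow overlaps are relaxed away."""
    if not centers:
        return True
    h = DEFAULT_BIRTH_LENGTH / 2.0
    p1 = np.asarray(centers) - h * np.asarray(axes)
    q1 = np.asarray(centers) + h * np.asarray(axes)
    p2 = np.broadcast_to(center - h * axis, p1.shape)
    q2 = np.broadcast_to(center + h * axis, p1.shape)
    dist, *_ = segment_segment_distance(p1, q1, p2, q2)
    return (dist - 2 * DEFAULT_RADIUS).min() > min_gap


def _settle(sim: Simulation, passes: int = 5):
    for _ in range(passes):
        sim.relax_population()


def _count_present(pop: Population) -> int:
    return pop.count(CellState.ALIVE, CellState.VICTIM)


def run_disc2d(cfg: RunConfig | None = None, **overrides) -> Trajectory:
    """2D disc competition; terminates when living + victim count exceeds
    ``population_cap`` (or at the ``max_hours`` safety cap)."""
    if cfg is None:
        cfg = default_config("disc2d", **overrides)
    genotypes = cfg.build_genotypes()
    rng = np.random.default_rng(np.random.SeedSequence((cfg.seed, 0xD15C)))
    pop = Population(genotypes, clock=SimClock(dt=cfg.dt), rng_seed=cfg.seed)
    _scatter_disc(pop, cfg, rng)
    _desync_initial_sizes(pop, rng)
    sim = Simulation(
        pop, growth_params=_growth_params(cfg), mechanics_params=_mech_params(cfg),
        combat_params=CombatParams(deterministic_lysis=cfg.deterministic_lysis),
        walls=[], dims=2, seed=cfg.seed, snapshot_interval=cfg.snapshot_interval,
        log_firings=cfg.log_firings, combat_first=cfg.combat_first)
    _settle(sim)
    sim._maybe_snapshot(force=True)  # snapshot the settled inoculum
    cap = cfg.population_cap
    return sim.run(max_hours=cfg.max_hours,
                   stop_when=lambda p: _count_present(p) > cap)


def _slough_rule(height: float):
    def rule(pop: Population):
        keep = pop.center[:, 2] <= height
        return keep, "SLOUGH"

    return rule


def run_biofilm3d(cfg: RunConfig | None = None, **overrides) -> Trajectory:
    """3D biofilm competition in a walled box with a cell slougher."""
    if cfg is None:
        cfg = default_config("biofilm3d", **overrides)
    genotypes = cfg.build_genotypes()
    rng = np.random.default_rng(np.random.SeedSequence((cfg.seed, 0xB10F)))
    pop = Population(genotypes, clock=SimClock(dt=cfg.dt), rng_seed=cfg.seed)
    w = cfg.box_base
    for g in genotypes[:2]:
        xy = rng.uniform(0.3 * w, 0.7 * w, size=2)
        theta = rng.uniform(0, 2 * np.pi)
        _make_cell(pop, g.id, [xy[0], xy[1], DEFAULT_RADIUS],
                   [np.cos(theta), np.sin(theta), 0.0], g.base_growth_rate)
    _desync_initial_sizes(pop, rng)
    walls = [
        Plane([0, 0, 0], [0, 0, 1]),           # floor
        Plane([0, 0, 0], [1, 0, 0]), Plane([w, 0, 0], [-1, 0, 0]),
        Plane([0, 0, 0], [0, 1, 0]), Plane([0, w, 0], [0, -1, 0]),
    ]
    sim = Simulation(
        pop, growth_params=_growth_params(cfg), mechanics_params=_mech_params(cfg),
        combat_params=CombatParams(deterministic_lysis=cfg.deterministic_lysis),
        walls=walls, dims=3, seed=cfg.seed, snapshot_interval=cfg.snapshot_interval,
        log_firings=cfg.log_firings, combat_first=cfg.combat_first,
        removal_rule=_slough_rule(cfg.slough_height))
    _settle(sim, passes=2)
    return sim.run(max_hours=cfg.duration)


def _exit_rule(length: float):
    def rule(pop: Population):
        keep = (pop.center[:, 0] >= 0.0) & (pop.center[:, 0] <= length)
        return keep, "EXIT"

    return rule


def _seed_chamber(pop: Population, cfg: RunConfig):
    genos = pop.genotypes
    att = next(g for g in genos if g.is_attacker)
    sus = next(g for g in genos if not g.is_attacker)
    cx, cy = cfg.chamber_length / 2.0, cfg.chamber_width / 2.0
    _make_cell(pop, sus.id, [cx, cy, 0.0], [1, 0, 0], sus.base_growth_rate)
    # two rows of five attackers abutting the central cell on either side;
    # each row is a contiguous width-spanning plug (cells end-to-end along
    # y), so the prey cannot leak through gaps within a row
    n_row = 5
    cell_span = DEFAULT_BIRTH_LENGTH + 2 * DEFAULT_RADIUS
    x_off = 0.5 * cell_span + DEFAULT_RADIUS + 0.05
    for sign in (-1.0, 1.0):
        for k in range(n_row):
            y = (k + 0.5) * cfg.chamber_width / n_row
            _make_cell(pop, att.id, [cx + sign * x_off, y, 0.0], [0, 1, 0],
                       att.base_growth_rate)


def run_chamber(cfg: RunConfig | None = None, **overrides) -> Trajectory:
    """Open-ended microfluidic chamber competition.

    The fixed inoculum grows for ``burn_in`` hours; the clock is then reset
    so the trajectory starts at t = 0 in the grown state, and the
    competition runs for ``duration`` hours.  Mechanical growth restriction
    defaults to 1/gamma = 0.1 in this geometry.
    """
    if cfg is None:
        cfg = default_config("chamber", **overrides)
    if cfg.growth.restriction_strength == 0.0:
        cfg.growth.restriction_strength = 0.1
    # chamber-specific solver defaults: sustained expulsion through the open
    # ends needs long-range displacement per relaxation pass (small alpha)
    # and a deeper resolution budget than the disc protocol
    if cfg.mechanics.alpha == 1.0:
        cfg.mechanics.alpha = 0.05
    if cfg.mechanics.max_resolution_iters == 10:
        cfg.mechanics.max_resolution_iters = 30
    # strain asymmetry of the microfluidic protocol: the susceptible prey
    # (E. coli-like) outgrows the attacker (A. baylyi-like); this is what
    # makes the growth restriction necessary in this geometry
    rates = {gc.is_attacker: gc.growth_rate for gc in cfg.genotypes}
    if rates.get(True) == 0.7 and rates.get(False) == 0.7:
        for gc in cfg.genotypes:
            if not gc.is_attacker:
                gc.growth_rate = 1.5  # ~28-min doubling; prey outgrows attacker
    genotypes = cfg.build_genotypes()
    rng = np.random.default_rng(np.random.SeedSequence((cfg.seed, 0xC4A8)))
    pop = Population(genotypes, clock=SimClock(dt=cfg.dt), rng_seed=cfg.seed)
    _seed_chamber(pop, cfg)
    _desync_initial_sizes(pop, rng)
    walls = [Plane([0, 0, 0], [0, 1, 0]),
             Plane([0, cfg.chamber_width, 0], [0, -1, 0])]
    exit_rule = _exit_rule(cfg.chamber_length)

    def make_sim(population, seed_salt):
        return Simulation(
            population, growth_params=_growth_params(cfg),
            mechanics_params=_mech_params(cfg),
            combat_params=CombatParams(deterministic_lysis=cfg.deterministic_lysis),
            walls=walls, dims=2, seed=cfg.seed + seed_salt,
            snapshot_interval=cfg.snapshot_interval, log_firings=cfg.log_firings,
            combat_first=cfg.combat_first, removal_rule=exit_rule)

    # burn-in: growth only (no firing) to fill the chamber from the inoculum
    burn_genos = [_disarmed(g) for g in genotypes]
    burn_pop = Population(burn_genos, clock=SimClock(dt=cfg.dt), rng_seed=cfg.seed)
    for i in range(pop.n):
        burn_pop.append_cell(pop.cell(i))
    burn_sim = make_sim(burn_pop, seed_salt=101)
    _settle(burn_sim)
    burn_sim.run(max_hours=cfg.burn_in)

    # competition: restore weapons, reset the clock to t = 0
    comp_pop = Population(genotypes, clock=SimClock(dt=cfg.dt), rng_seed=cfg.seed)
    for i in range(burn_pop.n):
        comp_pop.append_cell(burn_pop.cell(i))
    sim = make_sim(comp_pop, seed_salt=0)
    return sim.run(max_hours=cfg.duration)


def _disarmed(g):
    """A weaponless copy of a genotype, used during chamber burn-in."""
    from .cells import Genotype

    return Genotype(id=g.id, name=g.name, is_attacker=False, k_fire=0.0,
                    cost_coeff=g.cost_coeff, toxin_lysis_rate=g.toxin_lysis_rate,
                    lethal_hit_threshold=g.lethal_hit_threshold,
                    base_growth_rate=g.base_growth_rate)


def run_arena(cfg: RunConfig) -> Trajectory:
    runner = {"disc2d": run_disc2d, "biofilm3d": run_biofilm3d,
              "chamber": run_chamber}[cfg.arena]
    return runner(cfg)
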