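"""Deterministic generators of small test inputs.

Hand-placed capsule configurations (duels, single-file channels,
checkerboards, hexagonal discs), synthetic event logs with prescribed
death/boundary shapes, and toy taxonomies with planted effector
distributions.  These live in the package (not in the test tree) so the
CLI can demo on them; all are bit-reproducible from their arguments.
"""
from __future__ import annotations

import numpy as np
import pandas as pd

from .cells import Cell, CellState, Event, Genotype, Population, SimClock, Trajectory
from .growth import DEFAULT_BIRTH_LENGTH, DEFAULT_RADIUS
from .phylosig import AnnotatedTaxonomy

__all__ = [
    "duel_genotypes",
    "two_cell_duel",
    "single_file_chamber",
    "checkerboard_monolayer",
    "hex_disc",
    "make_cell_fixture",
    "make_synthetic_trajectory",
    "make_toy_taxonomy",
]


def duel_genotypes(k_fire: float = 50.0, k_lysis: float = 8.0, n_hits: int = 1,
                   cost_coeff: float = 0.001, growth_rate: float = 0.7):
    """The standard attacker/susceptible genotype pair used by fixtures."""
    return [
        Genotype(id=0, name="attacker", is_attacker=True, k_fire=k_fire,
                 cost_coeff=cost_coeff, toxin_lysis_rate=k_lysis,
                 lethal_hit_threshold=n_hits, base_growth_rate=growth_rate),
        Genotype(id=1, name="susceptible", is_attacker=False,
                 lethal_hit_threshold=n_hits, base_growth_rate=growth_rate),
    ]


def _pop(genotypes, cells, dt=0.025, seed=0):
    return Population.from_cells(cells, genotypes, clock=SimClock(dt=dt),
                                 rng_seed=seed)


def _cell(cid, gid, center, axis=(1, 0, 0), length=DEFAULT_BIRTH_LENGTH,
          radius=DEFAULT_RADIUS, state=CellState.ALIVE, growth_rate=0.7):
    axis = np.asarray(axis, float)
    return Cell(id=cid, genotype_id=gid, center=np.asarray(center, float),
                axis=axis / np.linalg.norm(axis), length=length, radius=radius,
                growth_rate=growth_rate, state=state)


def two_cell_duel(gap: float = 0.0, **geno_kwargs) -> Population:
    """One attacker and one susceptible, parallel, surfaces separated by
    ``gap`` (0 = exact contact)."""
    genos = duel_genotypes(**geno_kwargs)
    dy = 2 * DEFAULT_RADIUS + gap
    cells = [_cell(0, 0, [0, 0, 0]), _cell(1, 1, [0, dy, 0])]
    return _pop(genos, cells)


def single_file_chamber(n: int = 7, spacing_gap: float = 0.0,
                        alternating: bool = True, **geno_kwargs) -> Population:
    """Cells end-to-end along x in a one-cell-wide channel."""
    genos = duel_genotypes(**geno_kwargs)
    pitch = DEFAULT_BIRTH_LENGTH + 2 * DEFAULT_RADIUS + spacing_gap
    cells = []
    for k in range(n):
        gid = (k % 2) if alternating else (0 if k < n // 2 else 1)
        cells.append(_cell(k, gid, [k * pitch, 0, 0]))
    return _pop(genos, cells)


def checkerboard_monolayer(nx: int = 4, ny: int = 4, **geno_kwargs) -> Population:
    """Interleaved strains on a rectangular lattice at contact spacing."""
    genos = duel_genotypes(**geno_kwargs)
    px = DEFAULT_BIRTH_LENGTH + 2 * DEFAULT_RADIUS
    py = 2 * DEFAULT_RADIUS
    cells = []
    cid = 0
    for ix in range(nx):
        for iy in range(ny):
            cells.append(_cell(cid, (ix + iy) % 2, [ix * px, iy * py, 0]))
            cid += 1
    return _pop(genos, cells)


def hex_disc(rings: int = 3, **geno_kwargs) -> Population:
    """Hexagonally packed disc of near-spherical capsules at contact
    spacing: every interior cell has coordination number exactly 6."""
    genos = duel_genotypes(**geno_kwargs)
    a = 2 * DEFAULT_RADIUS  # lattice constant = touching spheres
    cells = []
    cid = 0
    for q in range(-rings, rings + 1):
        for r in range(max(-rings, -q - rings), min(rings, -q + rings) + 1):
            x = a * (q + r / 2.0)
            y = a * (np.sqrt(3) / 2.0) * r
            cells.append(_cell(cid, 0, [x, y, 0], length=1e-3))
            cid += 1
    return _pop(genos, cells)


def make_cell_fixture(kind: str, **kwargs) -> Population:
    builders = {
        "two_cell_duel": two_cell_duel,
        "single_file_chamber": single_file_chamber,
        "checkerboard_monolayer": checkerboard_monolayer,
        "hex_disc": hex_disc,
    }
    if kind not in builders:
        raise ValueError(f"unknown fixture kind {kind!r}")
    return builders[kind](**kwargs)


def make_synthetic_trajectory(shape: str = "linear", duration: float = 5.0,
                              snapshot_interval: float = 0.1,
                              rate: float = 12.0, step_deaths: int = 10,
                              step_time: float = 2.0, peak_rate: float = 40.0,
                              peak_time_h: float = 3.0, peak_width: float = 0.5,
                              n_boundary: float = 80.0):
    """Event log with a prescribed cumulative-death shape.

    ``shape``: ``linear`` (deaths at constant ``rate``), ``step``
    (``step_deaths`` deaths in one interval at ``step_time``), or
    ``peaked`` (Gaussian kill-rate bump of height ``peak_rate``).
    Returns ``(trajectory, n_boundary_series)``; snapshots hold empty
    populations (geometry-free), so metrics needing N_boundary must be
    given the returned series.
    """
    genos = duel_genotypes()
    traj = Trajectory(genos)
    times = np.arange(0.0, duration + 1e-9, snapshot_interval)
    for t in times:
        pop = Population(genos, clock=SimClock(t=t, dt=0.025))
        traj.snapshots.append((float(t), pop))
    if shape == "linear":
        cum = rate * times
    elif shape == "step":
        cum = np.where(times >= step_time, float(step_deaths), 0.0)
    elif shape == "peaked":
        from scipy.stats import norm

        cum = (peak_rate * peak_width * np.sqrt(2 * np.pi)
               * norm.cdf(times, loc=peak_time_h, scale=peak_width))
    else:
        raise ValueError(f"unknown shape {shape!r}")
    counts = np.floor(cum + 1e-9).astype(int)
    cid = 0
    for k in range(1, len(times)):
        for _ in range(counts[k] - counts[k - 1]):
            traj.events.append(Event(float(times[k]), "DEATH", 100000 + cid,
                                     0, aux=1.0))
            cid += 1
    return traj, np.full(len(times), float(n_boundary))


def make_toy_taxonomy(depth: int = 4, effector_archetypes=("X", "Y", "Z"),
                      p_random: float = 0.5, seed: int = 0,
                      clade_prefix: int = 1) -> AnnotatedTaxonomy:
    """Balanced binary taxonomy of ``2**depth`` species with planted
    effectors: ``X`` confined to one half-tree clade, ``Y`` present
    independently with probability ``p_random``, ``Z`` in one species only.

    Rank levels map onto tree depth: level 1 are the leaves themselves and
    each ascending level doubles clade size until the root (level >= depth+1).
    """
    rng = np.random.default_rng(seed)
    n = 2 ** depth
    species = [f"sp{k:03d}" for k in range(n)]
    levels: dict[int, list] = {}
    for lvl in range(1, 10):
        width = min(lvl - 1, depth)  # number of trailing tree levels merged
        labels = [f"L{lvl}c{k >> width}" for k in range(n)]
        levels[lvl] = labels
    presence: dict[str, set] = {s: set() for s in species}
    catalog = {}
    if "X" in effector_archetypes:
        clade = range(clade_prefix * n // 2, (clade_prefix + 1) * n // 2)
        for k in clade:
            presence[species[k]].add("X")
        catalog["X"] = "FAST"
    if "Y" in effector_archetypes:
        for k in range(n):
            if rng.uniform() < p_random:
                presence[species[k]].add("Y")
        catalog["Y"] = "FAST"
    if "Z" in effector_archetypes:
        presence[species[int(rng.integers(n))]].add("Z")
        catalog["Z"] = "SLOW"
    return AnnotatedTaxonomy(species, levels, presence, catalog=catalog)


def toy_rank_table(tax: AnnotatedTaxonomy) -> pd.DataFrame:
    """Rank-table view of a taxonomy (for IO round-trip tests and the CLI)."""
    from .phylosig import RANK_LEVELS

    data = {"species": tax.species}
    for lvl in range(3, 10):
        data[RANK_LEVELS[lvl]] = list(tax.levels[lvl])
    return pd.DataFrame(data)
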