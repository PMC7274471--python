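"""Domain types: cells, genotypes, populations, trajectories.

A :class:`Population` stores cell attributes in flat NumPy arrays
(structure-of-arrays) for speed; :class:`Cell` is the per-cell record used
at the API surface (snapshots, fixtures, inspection).
"""
from __future__ import annotations

from dataclasses import dataclass, field
from enum import IntEnum
from typing import Iterable, NamedTuple

import numpy as np

from .geometry import capsule_volume

__all__ = [
    "CellState",
    "Cell",
    "Genotype",
    "SimClock",
    "Population",
    "Event",
    "Trajectory",
]


class CellState(IntEnum):
    ALIVE = 0
    VICTIM = 1   # intoxicated past the lethal threshold; inert but solid
    REMOVED = 2  # lysed / sloughed / exited; no longer part of the geometry


@dataclass
class Genotype:
    """A strain: T6SS weapon parameters plus growth rate.

    Parameters
    ----------
    k_fire : float
        Mean needle firing rate, firings cell^-1 h^-1.
    cost_coeff : float
        Growth cost ``c`` per unit firing rate; a cell firing at rate
        ``k_fire`` grows at ``k_grow * (1 - c*k_fire)`` on average.
    toxin_lysis_rate : float
        ``k_lysis`` (h^-1); victims of this genotype's toxin are removed
        after a delay ``1/k_lysis``.
    lethal_hit_threshold : int
        ``N_hits``; hits (from any single non-kin genotype) needed to kill
        a cell of *this* genotype.
    """

    id: int
    name: str
    is_attacker: bool
    k_fire: float = 0.0
    cost_coeff: float = 0.0
    toxin_lysis_rate: float = 8.0
    lethal_hit_threshold: int = 1
    base_growth_rate: float = 0.7

    def __post_init__(self):
        if self.k_fire < 0:
            raise ValueError(f"genotype {self.name}: k_fire must be >= 0")
        if not self.is_attacker and self.k_fire != 0:
            raise ValueError(f"genotype {self.name}: non-attacker must have k_fire = 0")
        if self.lethal_hit_threshold < 1:
            raise ValueError(f"genotype {self.name}: lethal_hit_threshold must be >= 1")
        if self.is_attacker and self.toxin_lysis_rate <= 0:
            raise ValueError(f"genotype {self.name}: attacker needs toxin_lysis_rate > 0")
        if self.base_growth_rate < 0:
            raise ValueError(f"genotype {self.name}: base_growth_rate must be >= 0")


@dataclass
class Cell:
    """One spherocylindrical agent (API-surface record)."""

    id: int
    genotype_id: int
    center: np.ndarray
    axis: np.ndarray
    length: float          # cylindrical segment length, um
    radius: float          # um
    growth_rate: float     # k_grow,i, h^-1
    state: CellState = CellState.ALIVE
    birth_volume: float = float("nan")
    div_threshold: float = float("nan")  # 2*V0 + eta, cached at birth
    hit_tallies: dict = field(default_factory=dict)
    death_time: float = float("nan")
    lysis_delay: float = float("nan")

    @property
    def volume(self) -> float:
        return float(capsule_volume(self.length, self.radius))

    def validate(self):
        if abs(np.linalg.norm(self.axis) - 1.0) > 1e-8:
            raise ValueError(f"cell {self.id}: axis is not unit-norm")
        if self.state != CellState.REMOVED and not self.volume > 0:
            raise ValueError(f"cell {self.id}: non-positive volume")
        if self.state == CellState.VICTIM and np.isnan(self.death_time):
            raise ValueError(f"cell {self.id}: VICTIM without death_time")
        if any(v < 0 for v in self.hit_tallies.values()):
            raise ValueError(f"cell {self.id}: negative hit tally")


@dataclass
class SimClock:
    t: float = 0.0
    dt: float = 0.025
    t_start: float = 0.0
    t_end: float | None = None

    def __post_init__(self):
        if self.dt <= 0:
            raise ValueError("dt must be > 0")

    def advance(self):
        self.t += self.dt


class Population:
    """Structure-of-arrays container for the live simulation state.

    REMOVED cells are compacted away by the engine; rows present in the
    arrays are ALIVE or VICTIM.
    """

    _FLOAT_FIELDS = (
        "length", "radius", "growth_rate", "birth_volume", "div_threshold",
        "death_time", "lysis_delay", "pressure",
    )

    def __init__(self, genotypes: Iterable[Genotype], clock: SimClock | None = None,
                 rng_seed: int = 0):
        self.genotypes = list(genotypes)
        ids = [g.id for g in self.genotypes]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate genotype ids")
        self._geno_index = {g.id: k for k, g in enumerate(self.genotypes)}
        self.clock = clock if clock is not None else SimClock()
        self.rng_seed = rng_seed
        self._next_id = 0
        n_geno = len(self.genotypes)
        self.id = np.empty(0, dtype=np.int64)
        self.genotype = np.empty(0, dtype=np.int64)  # genotype *slot* index
        self.center = np.empty((0, 3), dtype=float)
        self.axis = np.empty((0, 3), dtype=float)
        self.state = np.empty(0, dtype=np.int8)
        self.tallies = np.empty((0, n_geno), dtype=np.int32)
        for name in self._FLOAT_FIELDS:
            setattr(self, name, np.empty(0, dtype=float))

    # -- construction -------------------------------------------------------

    @classmethod
    def from_cells(cls, cells: Iterable[Cell], genotypes: Iterable[Genotype],
                   clock: SimClock | None = None, rng_seed: int = 0) -> "Population":
        pop = cls(genotypes, clock=clock, rng_seed=rng_seed)
        for c in cells:
            pop.append_cell(c)
        return pop

    def append_cell(self, c: Cell) -> int:
        if c.genotype_id not in self._geno_index:
            raise ValueError(f"cell {c.id}: unknown genotype id {c.genotype_id}")
        idx = self.n
        self.id = np.append(self.id, c.id)
        self._next_id = max(self._next_id, c.id + 1)
        self.genotype = np.append(self.genotype, self._geno_index[c.genotype_id])
        self.center = np.vstack([self.center, np.asarray(c.center, float)[None, :]])
        axis = np.asarray(c.axis, float)
        self.axis = np.vstack([self.axis, axis[None, :]])
        self.state = np.append(self.state, np.int8(int(c.state)))
        row = np.zeros((1, len(self.genotypes)), dtype=np.int32)
        for gid, cnt in c.hit_tallies.items():
            row[0, self._geno_index[gid]] = cnt
        self.tallies = np.vstack([self.tallies, row])
        birth_vol = c.birth_volume if np.isfinite(c.birth_volume) else c.volume
        vals = dict(
            length=c.length, radius=c.radius, growth_rate=c.growth_rate,
            birth_volume=birth_vol,
            div_threshold=c.div_threshold if np.isfinite(c.div_threshold) else 2.0 * birth_vol,
            death_time=c.death_time, lysis_delay=c.lysis_delay, pressure=0.0,
        )
        for name in self._FLOAT_FIELDS:
            setattr(self, name, np.append(getattr(self, name), vals[name]))
        return idx

    def new_cell_id(self) -> int:
        self._next_id += 1
        return self._next_id - 1

    # -- views --------------------------------------------------------------

    @property
    def n(self) -> int:
        return len(self.id)

    @property
    def volume(self) -> np.ndarray:
        return capsule_volume(self.length, self.radius)

    @property
    def half_extent(self) -> np.ndarray:
        """Half of the total end-to-end length."""
        return 0.5 * self.length + self.radius

    def endpoints(self):
        """Cap-center endpoints of every capsule axis segment: (pa, pb)."""
        off = (0.5 * self.length)[:, None] * self.axis
        return self.center - off, self.center + off

    @property
    def genotype_ids(self) -> np.ndarray:
        return np.array([self.genotypes[k].id for k in self.genotype])

    def geno_slot(self, genotype_id: int) -> int:
        return self._geno_index[genotype_id]

    @property
    def attacker_mask(self) -> np.ndarray:
        is_att = np.array([g.is_attacker for g in self.genotypes], dtype=bool)
        return is_att[self.genotype]

    def mask(self, state: CellState) -> np.ndarray:
        return self.state == int(state)

    def count(self, *states: CellState) -> int:
        keep = np.zeros(self.n, dtype=bool)
        for s in states:
            keep |= self.state == int(s)
        return int(keep.sum())

    def cell(self, idx: int) -> Cell:
        gid = self.genotypes[self.genotype[idx]].id
        tallies = {self.genotypes[k].id: int(v)
                   for k, v in enumerate(self.tallies[idx]) if v}
        return Cell(
            id=int(self.id[idx]), genotype_id=gid,
            center=self.center[idx].copy(), axis=self.axis[idx].copy(),
            length=float(self.length[idx]), radius=float(self.radius[idx]),
            growth_rate=float(self.growth_rate[idx]),
            state=CellState(int(self.state[idx])),
            birth_volume=float(self.birth_volume[idx]),
            div_threshold=float(self.div_threshold[idx]),
            hit_tallies=tallies,
            death_time=float(self.death_time[idx]),
            lysis_delay=float(self.lysis_delay[idx]),
        )

    def cells(self) -> list[Cell]:
        return [self.cell(i) for i in range(self.n)]

    # -- mutation -----------------------------------------------------------

    def compact(self, keep_mask: np.ndarray):
        """Drop rows where ``keep_mask`` is False."""
        self.id = self.id[keep_mask]
        self.genotype = self.genotype[keep_mask]
        self.center = self.center[keep_mask]
        self.axis = self.axis[keep_mask]
        self.state = self.state[keep_mask]
        self.tallies = self.tallies[keep_mask]
        for name in self._FLOAT_FIELDS:
            setattr(self, name, getattr(self, name)[keep_mask])

    def copy(self) -> "Population":
        pop = Population(self.genotypes, clock=SimClock(self.clock.t, self.clock.dt,
                                                        self.clock.t_start, self.clock.t_end),
                         rng_seed=self.rng_seed)
        pop._next_id = self._next_id
        pop.id = self.id.copy()
        pop.genotype = self.genotype.copy()
        pop.center = self.center.copy()
        pop.axis = self.axis.copy()
        pop.state = self.state.copy()
        pop.tallies = self.tallies.copy()
        for name in self._FLOAT_FIELDS:
            setattr(pop, name, getattr(self, name).copy())
        return pop

    def check_finite(self):
        bad = ~(np.isfinite(self.center).all(axis=1)
                & np.isfinite(self.axis).all(axis=1)
                & np.isfinite(self.length) & (self.length >= 0))
        if bad.any():
            raise FloatingPointError(
                f"non-finite geometry for cell id(s) {self.id[bad][:5].tolist()}")


class Event(NamedTuple):
    t: float
    kind: str        # FIRE | HIT | DEATH | LYSIS | DIVIDE | SLOUGH | EXIT
    cell_id: int
    genotype_id: int  # for HIT/DEATH: the *attacking* genotype; else own
    aux: float = 0.0


class Trajectory:
    """Time-ordered population snapshots plus the full event log."""

    def __init__(self, genotypes: Iterable[Genotype]):
        self.genotypes = list(genotypes)
        self.snapshots: list[tuple[float, Population]] = []
        self.events: list[Event] = []

    @property
    def snapshot_times(self) -> np.ndarray:
        return np.array([t for t, _ in self.snapshots])

    def add_snapshot(self, pop: Population):
        self.snapshots.append((pop.clock.t, pop.copy()))

    def log(self, *events: Event):
        self.events.extend(events)

    def events_of_kind(self, kind: str) -> list[Event]:
        return [e for e in self.events if e.kind == kind]

    def final_population(self) -> Population:
        return self.snapshots[-1][1]

    def events_dataframe(self):
        import pandas as pd

        return pd.DataFrame(self.events, columns=Event._fields)
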