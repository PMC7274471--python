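"""The per-timestep update loop composing combat, growth, division,
relaxation and arena boundary actions.

Step order (combat first, since firing happens in essentially static
configurations): (1) firing/hits/intoxication and lysis bookkeeping,
(2) growth with weapon costs and crowding restriction, (3) division,
(4) mechanical relaxation, (5) arena removal rules, (6) clock advance.
All randomness flows from one seed through per-module substreams, so a
(config, seed) pair fully determines the trajectory.
"""
from __future__ import annotations

import numpy as np

from . import combat as _combat
from .cells import CellState, Event, Population, Trajectory
from .combat import CombatParams
from .growth import GrowthParams, divide_population, grow_population
from .mechanics import MechanicsParams, Plane, relax

__all__ = ["Simulation"]


class Simulation:
    """Drives one run; owns the population, parameter bundles and RNG streams."""

    def __init__(self, population: Population,
                 growth_params: GrowthParams | None = None,
                 mechanics_params: MechanicsParams | None = None,
                 combat_params: CombatParams | None = None,
                 walls: list[Plane] | None = None,
                 dims: int = 2,
                 nominal_v0: float | None = None,
                 seed: int | None = None,
                 snapshot_interval: float = 0.1,
                 log_firings: bool = False,
                 combat_first: bool = True,
                 removal_rule=None):
        self.pop = population
        self.growth_params = growth_params or GrowthParams()
        self.mechanics_params = mechanics_params or MechanicsParams()
        self.combat_params = combat_params or CombatParams()
        self.walls = walls or []
        self.dims = dims
        if nominal_v0 is None:
            from .growth import DEFAULT_BIRTH_VOLUME

            nominal_v0 = DEFAULT_BIRTH_VOLUME
        self.nominal_v0 = nominal_v0
        if seed is None:
            seed = population.rng_seed
        ss = np.random.SeedSequence(seed)
        kids = ss.spawn(3)
        self.rng_combat = np.random.default_rng(kids[0])
        self.rng_growth = np.random.default_rng(kids[1])
        self.rng_misc = np.random.default_rng(kids[2])
        self.snapshot_interval = snapshot_interval
        self.log_firings = log_firings
        self.combat_first = combat_first
        self.removal_rule = removal_rule  # callable(pop) -> (keep_mask, kind)
        self.trajectory = Trajectory(population.genotypes)
        self._next_snapshot = population.clock.t
        self._maybe_snapshot(force=True)

    # -- phases --------------------------------------------------------------

    def _sample_firings_phase(self):
        """Draw per-attacker firing counts; returns (cost, firer_rows, counts)
        with the cost multiplier aligned to current population rows."""
        pop = self.pop
        now = pop.clock.t
        dt = pop.clock.dt
        cost = np.ones(pop.n)
        events: list[Event] = []
        firer_rows, firer_counts = [], []
        for k, g in enumerate(pop.genotypes):
            if not g.is_attacker:
                continue
            rows = np.flatnonzero((pop.genotype == k)
                                  & (pop.state == int(CellState.ALIVE)))
            if len(rows) == 0:
                continue
            counts = _combat.sample_firings(g.k_fire, dt, self.rng_combat,
                                            n=len(rows))
            cost[rows] = _combat.firing_cost(counts, dt, g.cost_coeff)
            firer_rows.append(rows)
            firer_counts.append(counts)
            if self.log_firings:
                for r, c in zip(rows, counts):
                    if c:
                        events.append(Event(now, "FIRE", int(pop.id[r]),
                                            g.id, float(c)))
        self.trajectory.log(*events)
        if firer_rows:
            return cost, np.concatenate(firer_rows), np.concatenate(firer_counts)
        return cost, np.empty(0, np.int64), np.empty(0, np.int64)

    def _resolve_combat_phase(self, rows, counts) -> np.ndarray:
        """Fire the sampled needles, intoxicate, and clear due lysis.

        Returns the keep-mask that compacted away removed cells, so callers
        can realign any row-indexed arrays.
        """
        pop = self.pop
        now = pop.clock.t
        events: list[Event] = []
        firer_idx = np.repeat(rows, counts)
        if len(firer_idx):
            origins, dirs, lens = _combat.construct_needles(
                pop, firer_idx, self.rng_combat)
            struck = _combat.resolve_hits(pop, origins, dirs, lens, firer_idx)
            hit = struck >= 0
            assert not (struck[hit] == firer_idx[hit]).any(), \
                "needle struck its own firer"
            events += _combat.apply_intoxication(
                pop, struck[hit], pop.genotype[firer_idx[hit]], now,
                self.rng_combat, self.combat_params)
        events += _combat.advance_lysis(pop, now)
        self.trajectory.log(*events)
        return self._drop_removed()

    def _combat_phase(self) -> np.ndarray:
        """Firing/hits/intoxication/lysis; returns the per-cell growth-cost
        multiplier, realigned to the compacted population."""
        cost, rows, counts = self._sample_firings_phase()
        keep = self._resolve_combat_phase(rows, counts)
        return cost[keep]

    def _growth_phase(self, cost: np.ndarray, divide: bool = True):
        grow_population(self.pop, self.pop.clock.dt, cost, self.growth_params)
        if divide:
            self._division_phase()

    def _division_phase(self):
        events = divide_population(self.pop, self.growth_params, self.nominal_v0,
                                   self.rng_growth, dims=self.dims)
        self.trajectory.log(*events)

    def _removal_phase(self):
        if self.removal_rule is None:
            return
        keep, kind = self.removal_rule(self.pop)
        gone = np.flatnonzero(~keep)
        if len(gone):
            now = self.pop.clock.t
            self.trajectory.log(*[
                Event(now, kind, int(self.pop.id[i]),
                      self.pop.genotypes[self.pop.genotype[i]].id)
                for i in gone])
            self.pop.compact(keep)

    def _drop_removed(self) -> np.ndarray:
        keep = self.pop.state != int(CellState.REMOVED)
        if not keep.all():
            self.pop.compact(keep)
        return keep

    def _maybe_snapshot(self, force: bool = False):
        if force or self.pop.clock.t >= self._next_snapshot - 1e-9:
            if (self.trajectory.snapshots
                    and abs(self.trajectory.snapshots[-1][0] - self.pop.clock.t) < 1e-9):
                self.trajectory.snapshots[-1] = (self.pop.clock.t, self.pop.copy())
            else:
                self.trajectory.add_snapshot(self.pop)
            while self._next_snapshot <= self.pop.clock.t + 1e-9:
                self._next_snapshot += self.snapshot_interval

    # -- public --------------------------------------------------------------

    def relax_population(self):
        """One mechanical relaxation pass (used to settle inocula)."""
        self.pop.pressure = relax(self.pop, self.mechanics_params,
                                  walls=self.walls, dims=self.dims)

    def step(self):
        """Advance one timestep; appends events/snapshots to the trajectory."""
        self.pop.check_finite()
        if self.combat_first:
            cost = self._combat_phase()
            self._growth_phase(cost)
        else:
            # growth-first ordering: the same sampled firings set this
            # step's growth cost and are then resolved against the grown
            # (but not yet divided) configuration
            cost, rows, counts = self._sample_firings_phase()
            self._growth_phase(cost, divide=False)
            self._resolve_combat_phase(rows, counts)
            self._division_phase()
        self.relax_population()
        self._removal_phase()
        self.pop.clock.advance()
        self._maybe_snapshot()
        return self.pop

    def run(self, max_hours: float | None = None,
            stop_when=None) -> Trajectory:
        """Step until ``stop_when(pop)`` is true or ``max_hours`` elapse."""
        t0 = self.pop.clock.t
        while True:
            if stop_when is not None and stop_when(self.pop):
                break
            if max_hours is not None and self.pop.clock.t - t0 >= max_hours - 1e-9:
                break
            self.step()
        self._maybe_snapshot(force=True)
        self.pop.clock.t_end = self.pop.clock.t
        return self.trajectory
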