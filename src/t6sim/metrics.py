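"""Quantitative readouts of competition trajectories.

Implements relative fitness, attacker frequency, interstrain-boundary
identification, boundary saturation, coordination/confluency, kill-rate
series, the normalized peak kill rate, Monte-Carlo hit probability, and
the barrier-discounted kill-rate prediction
``k_kill = (1 - f_boundary) * k_fire * p_hit``.

Conventions: "touching" reuses the mechanics contact threshold (0.01 um);
boundary cells are attacker cells touching at least one susceptible-strain
cell, living (ALIVE) or dead-but-unlysed (VICTIM); strain volumes in
relative fitness count ALIVE cells only.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import uniform_filter1d

from . import combat as _combat
from .cells import CellState, Population, Trajectory
from .mechanics import ContactGraph, detect_contacts

__all__ = [
    "MetricSeries",
    "UndefinedMetricError",
    "relative_fitness",
    "attacker_frequency",
    "boundary_cells",
    "boundary_saturation",
    "coordination_and_confluency",
    "kill_rate_series",
    "normalized_peak_kill_rate",
    "estimate_hit_probability",
    "predict_kill_rate",
    "compute_metric_series",
]

CONTACT_THRESHOLD = 0.01  # um


class UndefinedMetricError(ValueError):
    """Raised when a metric's value is mathematically undefined."""


@dataclass
class MetricSeries:
    times: np.ndarray
    n_boundary: np.ndarray
    boundary_saturation: np.ndarray
    cumulative_deaths: np.ndarray
    kill_rate: np.ndarray
    median_coordination: np.ndarray
    confluency_time: float | None
    t_max: float | None
    normalized_peak_kill_rate: float | None


def _strain_masks(pop: Population):
    att = pop.attacker_mask
    return att, ~att


def _living_volume(pop: Population, mask) -> float:
    keep = mask & (pop.state == int(CellState.ALIVE))
    return float(pop.volume[keep].sum())


def relative_fitness(trajectory: Trajectory) -> float:
    """log2 fold-change of attacker volume over that of the susceptible strain."""
    t0, start = trajectory.snapshots[0]
    t1, end = trajectory.snapshots[-1]
    att0, sus0 = _strain_masks(start)
    att1, sus1 = _strain_masks(end)
    va0, vs0 = _living_volume(start, att0), _living_volume(start, sus0)
    va1, vs1 = _living_volume(end, att1), _living_volume(end, sus1)
    if va0 <= 0 or vs0 <= 0:
        raise UndefinedMetricError("both strains need positive start volumes")
    den = np.log2(vs1 / vs0) if vs1 > 0 else None
    if den is None or den == 0:
        raise UndefinedMetricError("susceptible volume fold-change is degenerate")
    return float(np.log2(va1 / va0) / den)


def attacker_frequency(pop: Population) -> float:
    """Attacker living volume / total living volume."""
    if pop.n == 0:
        raise UndefinedMetricError("empty snapshot")
    att, _ = _strain_masks(pop)
    total = _living_volume(pop, np.ones(pop.n, dtype=bool))
    if total == 0:
        raise UndefinedMetricError("no living volume")
    return _living_volume(pop, att) / total


def _boundary_pairs(pop: Population, contacts: ContactGraph):
    """Attacker--susceptible contact pairs as (attacker_row, susceptible_row)."""
    att, sus = _strain_masks(pop)
    present = pop.state != int(CellState.REMOVED)
    att &= present
    sus &= present
    i, j = contacts.i, contacts.j
    m1 = att[i] & sus[j]
    m2 = att[j] & sus[i]
    a_rows = np.concatenate([i[m1], j[m2]])
    s_rows = np.concatenate([j[m1], i[m2]])
    return a_rows, s_rows


def boundary_cells(pop: Population, contacts: ContactGraph | None = None):
    """Attacker cells touching >= 1 susceptible-strain cell (living or dead).

    Returns ``(set of attacker cell ids, N_boundary)``.
    """
    if contacts is None:
        contacts = detect_contacts(pop, CONTACT_THRESHOLD)
    a_rows, _ = _boundary_pairs(pop, contacts)
    ids = set(pop.id[np.unique(a_rows)].tolist())
    return ids, len(ids)


def boundary_saturation(pop: Population, contacts: ContactGraph | None = None) -> float:
    """Fraction of boundary-attacker | susceptible contacts whose susceptible
    partner is dead (VICTIM); 0 when there are no such contacts."""
    if contacts is None:
        contacts = detect_contacts(pop, CONTACT_THRESHOLD)
    _, s_rows = _boundary_pairs(pop, contacts)
    if len(s_rows) == 0:
        return 0.0
    return float((pop.state[s_rows] == int(CellState.VICTIM)).mean())


def _median_coordination(pop: Population, contacts: ContactGraph | None = None) -> float:
    if pop.n == 0:
        return 0.0
    if contacts is None:
        contacts = detect_contacts(pop, CONTACT_THRESHOLD)
    present = pop.state != int(CellState.REMOVED)
    deg = contacts.degree(pop.n)
    return float(np.median(deg[present]))


def coordination_and_confluency(trajectory: Trajectory,
                                plateau_target: float = 5.0,
                                plateau_tol: float = 1.0,
                                window: float = 1.0):
    """Median coordination number per snapshot and the confluency time.

    Confluency is the first snapshot at which the median coordination
    number reaches ``plateau_target`` and stays within ``plateau_tol`` of
    its value there for ``window`` hours (or to the end of the run, if
    shorter).  Returns ``(times, medians, confluency_time_or_None)``.
    """
    times = trajectory.snapshot_times
    medians = np.array([_median_coordination(pop) for _, pop in trajectory.snapshots])
    conf_time = None
    for k, (t, m) in enumerate(zip(times, medians)):
        if m < plateau_target:
            continue
        in_window = (times >= t) & (times <= t + window)
        if np.all(np.abs(medians[in_window] - m) <= plateau_tol):
            conf_time = float(t)
            break
    return times, medians, conf_time


def _death_times(trajectory: Trajectory) -> np.ndarray:
    """Times of DEATH events of susceptible-strain (non-attacker) cells.

    DEATH events carry the victim's own genotype id in ``aux``.
    """
    attacker_geno = {g.id for g in trajectory.genotypes if g.is_attacker}
    return np.array(sorted(e.t for e in trajectory.events
                           if e.kind == "DEATH" and int(e.aux) not in attacker_geno))


def cumulative_deaths(trajectory: Trajectory) -> np.ndarray:
    """N_death(t) on the snapshot time grid."""
    times = trajectory.snapshot_times
    deaths = _death_times(trajectory)
    return np.searchsorted(deaths, times, side="right").astype(float)


def kill_rate_series(trajectory: Trajectory, smoothing_window: float = 0.25):
    """k_death(t): gradient of cumulative deaths, moving-average smoothed.

    Returns ``(times, k_death)``.
    """
    times = trajectory.snapshot_times
    n_death = cumulative_deaths(trajectory)
    if len(times) < 2:
        return times, np.zeros_like(times)
    k = np.gradient(n_death, times)
    dt = np.median(np.diff(times))
    size = max(1, int(round(smoothing_window / dt)))
    k = uniform_filter1d(k, size=size, mode="nearest")
    return times, np.maximum(k, 0.0)


def _n_boundary_series(trajectory: Trajectory) -> np.ndarray:
    return np.array([boundary_cells(pop)[1] for _, pop in trajectory.snapshots],
                    dtype=float)


def normalized_peak_kill_rate(trajectory: Trajectory,
                              smoothing_window: float = 0.25,
                              n_boundary: np.ndarray | None = None,
                              confluency_time: float | None = None) -> float:
    """Peak post-confluency kill rate per boundary attacker cell.

    ``t_max`` is the argmax of the *smoothed absolute* kill rate restricted
    to t >= confluency; the peak rate is then divided by N_boundary(t_max).
    (This is deliberately not the max of the pointwise-normalized series,
    which would be dominated by noisy pre-confluent killing.)
    """
    times, k = kill_rate_series(trajectory, smoothing_window)
    if confluency_time is None:
        _, _, confluency_time = coordination_and_confluency(trajectory)
    if confluency_time is None:
        raise UndefinedMetricError("confluency never reached")
    post = times >= confluency_time
    if not post.any() or np.all(k[post] == 0):
        return 0.0
    if n_boundary is None:
        n_boundary = _n_boundary_series(trajectory)
    k_post = np.where(post, k, -np.inf)
    imax = int(np.argmax(k_post))
    if n_boundary[imax] == 0:
        raise UndefinedMetricError("no boundary attacker cells at the kill-rate peak")
    return float(k[imax] / n_boundary[imax])


def peak_time(trajectory: Trajectory, smoothing_window: float = 0.25,
              confluency_time: float | None = None) -> float:
    times, k = kill_rate_series(trajectory, smoothing_window)
    if confluency_time is None:
        _, _, confluency_time = coordination_and_confluency(trajectory)
    if confluency_time is None:
        raise UndefinedMetricError("confluency never reached")
    k_post = np.where(times >= confluency_time, k, -np.inf)
    return float(times[int(np.argmax(k_post))])


def estimate_hit_probability(snapshots, needles_per_cell: int = 100,
                             rng=None, seed: int = 0) -> float:
    """Monte-Carlo probability that a boundary attacker's needle strikes a
    non-kin (susceptible or victim) cell, in frozen configurations.

    ``snapshots`` is a Population or an iterable of Populations; the value
    is the unweighted mean over configurations.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    if isinstance(snapshots, Population):
        snapshots = [snapshots]
    fractions = []
    for pop in snapshots:
        contacts = detect_contacts(pop, CONTACT_THRESHOLD)
        ids, n_b = boundary_cells(pop, contacts)
        if n_b == 0:
            continue
        rows = np.flatnonzero(np.isin(pop.id, list(ids)))
        firer_idx = np.repeat(rows, needles_per_cell)
        origins, dirs, lens = _combat.construct_needles(pop, firer_idx, rng)
        struck = _combat.resolve_hits(pop, origins, dirs, lens, firer_idx)
        hit = struck >= 0
        nonkin = np.zeros(len(struck), dtype=bool)
        nonkin[hit] = pop.genotype[struck[hit]] != pop.genotype[firer_idx[hit]]
        fractions.append(float(nonkin.mean()))
    if not fractions:
        raise UndefinedMetricError("no boundary attacker cells in any configuration")
    return float(np.mean(fractions))


def predict_kill_rate(f_boundary: float, k_fire: float, p_hit: float) -> float:
    """Barrier-discounted kill-rate prediction per boundary cell:
    ``(1 - f_boundary) * k_fire * p_hit``."""
    return (1.0 - f_boundary) * k_fire * p_hit


def compute_metric_series(trajectory: Trajectory,
                          smoothing_window: float = 0.25) -> MetricSeries:
    """Assemble the full per-time metric table for one trajectory."""
    times = trajectory.snapshot_times
    n_b = np.empty(len(times))
    sat = np.empty(len(times))
    for k, (_, pop) in enumerate(trajectory.snapshots):
        contacts = detect_contacts(pop, CONTACT_THRESHOLD)
        n_b[k] = boundary_cells(pop, contacts)[1]
        sat[k] = boundary_saturation(pop, contacts)
    _, medians, conf = coordination_and_confluency(trajectory)
    _, k_death = kill_rate_series(trajectory, smoothing_window)
    npkr = None
    t_max = None
    if conf is not None:
        try:
            npkr = normalized_peak_kill_rate(
                trajectory, smoothing_window, n_boundary=n_b, confluency_time=conf)
            t_max = peak_time(trajectory, smoothing_window, confluency_time=conf)
        except UndefinedMetricError:
            pass
    return MetricSeries(times=times, n_boundary=n_b, boundary_saturation=sat,
                        cumulative_deaths=cumulative_deaths(trajectory),
                        kill_rate=k_death, median_coordination=medians,
                        confluency_time=conf, t_max=t_max,
                        normalized_peak_kill_rate=npkr)
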