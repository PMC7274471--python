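"""Shared fixtures and independent oracles.

Expensive simulation grids are session-scoped and shared across tests;
they are reduced to lightweight summaries (metrics plus final populations)
so memory stays bounded.
"""
from __future__ import annotations

import warnings

import numpy as np
import pytest

warnings.filterwarnings("ignore", category=RuntimeWarning, module="t6sim")


# ---------------------------------------------------------------------------
# Independent geometric oracle: segment-segment distance via exhaustive KKT
# case analysis of the box-constrained 2-variable quadratic (interior, four
# edges, four corners) -- structurally unrelated to the library routine.
# ---------------------------------------------------------------------------

def oracle_segment_distance(p1, q1, p2, q2):
    p1, q1, p2, q2 = (np.asarray(v, float) for v in (p1, q1, p2, q2))
    u = q1 - p1
    v = q2 - p2
    w = p1 - p2

    def f(s, t):
        d = w + s * u - t * v
        return float(np.dot(d, d))

    candidates = []
    a, b, c = np.dot(u, u), np.dot(u, v), np.dot(v, v)
    d_, e_ = np.dot(u, w), np.dot(v, w)
    det = a * c - b * b
    if det > 1e-15:  # interior stationary point
        s = (b * e_ - c * d_) / det
        t = (a * e_ - b * d_) / det
        if 0 <= s <= 1 and 0 <= t <= 1:
            candidates.append((s, t))
    for s in (0.0, 1.0):  # edges s fixed
        if c > 1e-15:
            t = np.clip((e_ + s * b) / c, 0.0, 1.0)
            candidates.append((s, t))
    for t in (0.0, 1.0):  # edges t fixed
        if a > 1e-15:
            s = np.clip((t * b - d_) / a, 0.0, 1.0)
            candidates.append((s, t))
    candidates += [(0, 0), (0, 1), (1, 0), (1, 1)]
    best = min(candidates, key=lambda st: f(*st))
    return np.sqrt(f(*best)), best[0], best[1]


def oracle_capsule_gap(pop, i, j):
    pa, pb = pop.endpoints()
    dist, _, _ = oracle_segment_distance(pa[i], pb[i], pa[j], pb[j])
    return dist - (pop.radius[i] + pop.radius[j])


def random_capsule_population(n, box=12.0, seed=0, length_range=(0.5, 2.5)):
    from t6sim.cells import Cell, Population, SimClock
    from t6sim.fixtures import duel_genotypes

    rng = np.random.default_rng(seed)
    genos = duel_genotypes()
    cells = []
    for k in range(n):
        axis = rng.normal(size=3)
        axis[2] = 0.0
        axis /= np.linalg.norm(axis)
        cells.append(Cell(
            id=k, genotype_id=int(k % 2),
            center=np.array([*rng.uniform(0, box, 2), 0.0]),
            axis=axis, length=float(rng.uniform(*length_range)), radius=0.5,
            growth_rate=0.7))
    return Population.from_cells(cells, genos, clock=SimClock(dt=0.025))


# ---------------------------------------------------------------------------
# Session-scoped simulation grids (desk scale; see docs/methods.md)
# ---------------------------------------------------------------------------

SMALL_DISC = dict(disc_diameter=60.0, inoculum_size=36, population_cap=1100)


def _run_small_disc(k_fire, k_lysis, seed, n_hits=1, cost=0.001):
    """Reduced-arena disc run at the inoculum density of the full protocol."""
    from t6sim import default_config, run_disc2d

    cfg = default_config("disc2d", k_fire=float(k_fire), k_lysis=float(k_lysis),
                         n_hits=n_hits, cost_coeff=cost)
    cfg.disc_diameter = SMALL_DISC["disc_diameter"]
    cfg.inoculum_size = SMALL_DISC["inoculum_size"]
    cfg.population_cap = SMALL_DISC["population_cap"]
    cfg.seed = int(seed)
    return run_disc2d(cfg)


def _victim_hit_fraction_trace(traj, bin_hours=1.0):
    """Per-time-bin fraction of *non-kin* needle hits that were absorbed by
    already-dead (victim) cells.  HIT events encode the target in ``aux``:
    +2 non-kin, +1 dead at impact."""
    hits = [(e.t, e.aux) for e in traj.events if e.kind == "HIT" and e.aux >= 2]
    if not hits:
        return np.empty(0), np.empty(0)
    t = np.array([h[0] for h in hits])
    on_victim = np.array([h[1] == 3 for h in hits], dtype=float)
    edges = np.arange(0.0, t.max() + bin_hours, bin_hours)
    centers, fracs = [], []
    for lo, hi in zip(edges[:-1], edges[1:]):
        m = (t >= lo) & (t < hi)
        if m.sum() >= 20:
            centers.append(0.5 * (lo + hi))
            fracs.append(on_victim[m].mean())
    return np.array(centers), np.array(fracs)


def _summarize(traj, keep_pop=False):
    from t6sim import metrics as M

    series = M.compute_metric_series(traj)
    out = {
        "final_attacker_frequency": M.attacker_frequency(traj.final_population()),
        "final_saturation": float(series.boundary_saturation[-1]),
        "confluency_time": series.confluency_time,
        "npkr": series.normalized_peak_kill_rate,
        "t_max": series.t_max,
        "times": series.times,
        "saturation": series.boundary_saturation,
        "median_coordination": series.median_coordination,
        "n_boundary": series.n_boundary,
    }
    if series.t_max is not None:
        idx = int(np.argmin(np.abs(series.times - series.t_max)))
        out["saturation_at_peak"] = float(series.boundary_saturation[idx])
    out["victim_hit_fraction"] = _victim_hit_fraction_trace(traj)
    if keep_pop:
        out["final_pop"] = traj.final_population()
    return out


@pytest.fixture(scope="session")
def small_disc_grid():
    """k_fire x k_lysis grid of reduced-arena disc competitions.

    Serves the optimum-firing-rate, kill-rate-prediction and saturation-
    monotonicity checks.
    """
    grid = {}
    for k_lysis in (0.8, 8.0):
        for k_fire in (0.0, 12.5, 25.0, 50.0, 100.0, 150.0, 250.0):
            for seed in (0, 1):
                traj = _run_small_disc(k_fire, k_lysis, seed)
                grid[(k_fire, k_lysis, seed)] = _summarize(
                    traj, keep_pop=(k_fire in (50.0, 150.0) and seed == 0))
                del traj
    return grid


@pytest.fixture(scope="session")
def disc150_slow_runs():
    """Full-protocol disc runs (100-um disc, cap 3000) at k_fire = 150,
    slow lysis: the boundary-saturation and coordination-plateau setup."""
    from t6sim import default_config, run_disc2d

    out = {}
    for seed in (0, 1, 2, 3, 4):
        cfg = default_config("disc2d", k_fire=150.0, k_lysis=0.8)
        cfg.population_cap = 3000
        cfg.seed = seed
        traj = run_disc2d(cfg)
        out[seed] = _summarize(traj, keep_pop=(seed in (0, 1)))
        del traj
    return out


@pytest.fixture(scope="session")
def nhits_collapse_runs():
    """Reduced-arena runs for the k_fire/N_hits collapse and cost-invariance
    checks of the normalized peak kill rate.

    Run at the rapid-lysis rate, where the peak kill rate spans almost an
    order of magnitude across firing rates and the collapse is therefore
    statistically discriminable; at slow lysis the curve saturates and all
    conditions coincide within replicate noise.
    """
    runs = {}
    for n_hits, k_fire in ((2, 100.0), (4, 200.0)):
        for seed in (0, 1):
            traj = _run_small_disc(k_fire, 8.0, seed, n_hits=n_hits)
            runs[("nhits", n_hits, k_fire, seed)] = _summarize(traj)
            del traj
    for cost in (0.0, 0.004):
        for seed in (0, 1):
            traj = _run_small_disc(150.0, 8.0, seed, cost=cost)
            runs[("cost", cost, seed)] = _summarize(traj)
            del traj
    return runs


@pytest.fixture(scope="session")
def chamber_pair_runs():
    """Paired-seed chamber competitions under rapid vs slow victim lysis."""
    from t6sim import default_config
    from t6sim.arenas import run_chamber
    from t6sim.geometry import capsule_projected_area

    def occupancy_series(traj, area):
        out = []
        for t, pop in traj.snapshots:
            m = (~pop.attacker_mask) & (pop.state == 0)
            out.append((t, float(capsule_projected_area(
                pop.length[m], pop.radius[m]).sum() / area)))
        return out

    runs = {}
    for k_lysis in (0.8, 8.0):
        for seed in (0, 1):
            cfg = default_config("chamber", k_fire=50.0, k_lysis=k_lysis)
            cfg.duration = 5.0
            cfg.seed = seed
            traj = run_chamber(cfg)
            area = cfg.chamber_length * cfg.chamber_width
            runs[(k_lysis, seed)] = occupancy_series(traj, area)
            del traj
    return runs
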