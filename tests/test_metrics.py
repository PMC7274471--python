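"""Metric operations on hand-built and synthetic inputs."""
import numpy as np
import pytest

from t6sim.cells import CellState, Population, SimClock, Trajectory
from t6sim.fixtures import (
    checkerboard_monolayer,
    duel_genotypes,
    hex_disc,
    make_synthetic_trajectory,
    single_file_chamber,
    two_cell_duel,
)
from t6sim import metrics as M
from t6sim.geometry import cyl_length_for_volume
from t6sim.mechanics import detect_contacts


def trajectory_with_volumes(att0, sus0, att1, sus1):
    """Two-snapshot trajectory with prescribed per-strain volumes."""
    genos = duel_genotypes()
    traj = Trajectory(genos)
    for t, (va, vs) in ((0.0, (att0, sus0)), (5.0, (att1, sus1))):
        pop = two_cell_duel(gap=3.0)
        pop.clock = SimClock(t=t)
        pop.length[0] = cyl_length_for_volume(va, pop.radius[0])
        pop.length[1] = cyl_length_for_volume(vs, pop.radius[1])
        traj.snapshots.append((t, pop))
    return traj


class TestRelativeFitness:
    def test_symmetric_doubling_is_one(self):
        traj = trajectory_with_volumes(2.0, 2.0, 4.0, 4.0)
        assert M.relative_fitness(traj) == pytest.approx(1.0)

    def test_log2_ratio(self):
        traj = trajectory_with_volumes(2.0, 2.0, 8.0, 4.0)  # x4 vs x2
        assert M.relative_fitness(traj) == pytest.approx(2.0)
        traj = trajectory_with_volumes(2.0, 2.0, 4.0, 16.0)  # x2 vs x8
        assert M.relative_fitness(traj) == pytest.approx(1 / 3)

    def test_unchanged_susceptible_is_undefined(self):
        traj = trajectory_with_volumes(2.0, 2.0, 4.0, 2.0)
        with pytest.raises(M.UndefinedMetricError):
            M.relative_fitness(traj)


class TestAttackerFrequency:
    def test_even_mix(self):
        pop = two_cell_duel()
        assert M.attacker_frequency(pop) == pytest.approx(0.5)

    def test_three_cell_arithmetic(self):
        # attacker volume 2, susceptibles 1 + 1 -> frequency 0.5
        from t6sim.cells import Cell

        genos = duel_genotypes()
        cells = []
        for k, (gid, vol, y) in enumerate([(0, 2.0, 0.0), (1, 1.0, 3.0),
                                           (1, 1.0, 6.0)]):
            cells.append(Cell(
                id=k, genotype_id=gid, center=np.array([0.0, y, 0.0]),
                axis=np.array([1.0, 0.0, 0.0]),
                length=float(cyl_length_for_volume(vol, 0.5)), radius=0.5,
                growth_rate=0.7))
        pop = Population.from_cells(cells, genos)
        assert M.attacker_frequency(pop) == pytest.approx(0.5)

    def test_victims_excluded(self):
        pop = two_cell_duel()
        pop.state[1] = int(CellState.VICTIM)
        assert M.attacker_frequency(pop) == pytest.approx(1.0)


class TestBoundary:
    def test_segregated_groups_have_empty_boundary(self):
        pop = two_cell_duel(gap=10.0)
        ids, n = M.boundary_cells(pop)
        assert (ids, n) == (set(), 0)

    def test_single_touching_pair(self):
        pop = two_cell_duel(gap=0.0)
        ids, n = M.boundary_cells(pop)
        assert n == 1 and ids == {0}

    def test_checkerboard_matches_contact_scan(self):
        pop = checkerboard_monolayer(4, 4)
        contacts = detect_contacts(pop, 0.01)
        ids, n = M.boundary_cells(pop, contacts)
        att_rows = np.flatnonzero(pop.attacker_mask)
        expected = set()
        for i in att_rows:
            for j in np.flatnonzero(~pop.attacker_mask):
                from conftest import oracle_capsule_gap

                if oracle_capsule_gap(pop, int(i), int(j)) <= 0.01:
                    expected.add(int(pop.id[i]))
        assert ids == expected
        # every attacker in a 4x4 checkerboard touches a susceptible
        assert n == len(att_rows)

    def test_dead_partners_count_for_boundary(self):
        pop = two_cell_duel(gap=0.0)
        pop.state[1] = int(CellState.VICTIM)
        assert M.boundary_cells(pop)[1] == 1


class TestBoundarySaturation:
    def test_no_victims_zero(self):
        pop = checkerboard_monolayer(3, 3)
        assert M.boundary_saturation(pop) == 0.0

    def test_all_dead_one(self):
        pop = two_cell_duel(gap=0.0)
        pop.state[1] = int(CellState.VICTIM)
        assert M.boundary_saturation(pop) == 1.0

    def test_quarter_dead_fixture(self):
        # one attacker touching 4 susceptibles laterally, one of them dead
        from t6sim.cells import Cell

        genos = duel_genotypes()
        cells = [Cell(id=0, genotype_id=0, center=np.zeros(3),
                      axis=np.array([1.0, 0, 0]), length=1.0, radius=0.5,
                      growth_rate=0.7)]
        for k, (dx, dy) in enumerate([(0, 1.0), (0, -1.0), (2.0, 0), (-2.0, 0)]):
            cells.append(Cell(id=k + 1, genotype_id=1,
                              center=np.array([dx, dy, 0.0]),
                              axis=np.array([1.0, 0, 0]), length=1.0,
                              radius=0.5, growth_rate=0.7))
        pop = Population.from_cells(cells, genos)
        pop.state[1] = int(CellState.VICTIM)
        assert M.boundary_saturation(pop) == pytest.approx(0.25)


class TestCoordination:
    def test_lone_cell(self):
        pop = two_cell_duel(gap=5.0)
        pop.compact(np.array([True, False]))
        traj = Trajectory(pop.genotypes)
        traj.snapshots.append((0.0, pop))
        _, med, conf = M.coordination_and_confluency(traj)
        assert med[0] == 0.0 and conf is None

    def test_three_collinear_rods_median_one(self):
        pop = single_file_chamber(3, alternating=False)
        traj = Trajectory(pop.genotypes)
        traj.snapshots.append((0.0, pop))
        _, med, _ = M.coordination_and_confluency(traj)
        assert med[0] == 1.0  # degrees 1, 2, 1

    def test_hex_disc_interior_coordination_six(self):
        pop = hex_disc(rings=4)
        contacts = detect_contacts(pop, 0.01)
        deg = contacts.degree(pop.n)
        # interior = cells with full neighborhoods; median over all >= 5
        assert np.median(deg) >= 5
        center = np.argmin(np.linalg.norm(pop.center, axis=1))
        assert deg[center] == 6


class TestKillRateSeries:
    def test_no_deaths_zero(self):
        traj, _ = make_synthetic_trajectory("linear", rate=0.0)
        _, k = M.kill_rate_series(traj)
        assert np.allclose(k, 0.0)

    def test_linear_accumulation_constant_rate(self):
        traj, _ = make_synthetic_trajectory("linear", rate=12.0, duration=5.0)
        times, k = M.kill_rate_series(traj)
        interior = (times > 0.5) & (times < 4.5)
        # integer event counts make the raw gradient oscillate by one death
        # per interval; the smoothed series must still track the true rate
        assert k[interior].mean() == pytest.approx(12.0, rel=0.02)
        assert np.allclose(k[interior], 12.0, atol=3.5)

    def test_step_conserves_integrated_rate(self):
        traj, _ = make_synthetic_trajectory("step", step_deaths=10,
                                            step_time=2.0, duration=4.0)
        times, k = M.kill_rate_series(traj)
        total = np.trapezoid(k, times)
        assert total == pytest.approx(10.0, rel=0.05)


class TestNormalizedPeakKillRate:
    def test_zero_firing_run_zero(self):
        traj, nb = make_synthetic_trajectory("linear", rate=0.0)
        npkr = M.normalized_peak_kill_rate(traj, n_boundary=nb,
                                           confluency_time=1.0)
        assert npkr == 0.0

    def test_peak_40_over_80_boundary_cells(self):
        traj, nb = make_synthetic_trajectory("peaked", peak_rate=40.0,
                                             peak_time_h=3.0, n_boundary=80.0)
        npkr = M.normalized_peak_kill_rate(traj, n_boundary=nb,
                                           confluency_time=1.0)
        assert npkr == pytest.approx(0.5, rel=0.05)

    def test_post_confluency_peak_used_not_pointwise_max(self):
        """A pre-confluent bump with a huge pointwise-normalized value must
        not be returned: the peak is found on the absolute rate, post-
        confluency only."""
        traj, _ = make_synthetic_trajectory("peaked", peak_rate=40.0,
                                            peak_time_h=4.0, duration=6.0)
        times = traj.snapshot_times
        # early bump: 20 extra deaths around t = 1
        from t6sim.cells import Event

        for k, t in enumerate(times):
            if 0.9 <= t <= 1.1:
                for c in range(7):
                    traj.events.append(Event(float(t), "DEATH",
                                             500000 + k * 10 + c, 0, aux=1.0))
        # N_boundary tiny early (pointwise ratio large), big at the true peak
        nb = np.where(times < 2.0, 2.0, 80.0)
        npkr = M.normalized_peak_kill_rate(traj, n_boundary=nb,
                                           confluency_time=2.0)
        assert npkr == pytest.approx(40.0 / 80.0, rel=0.1)
        # the rejected alternative would have been ~ 20-deaths-bump / 2
        assert npkr < 1.0


class TestHitProbabilityAndPrediction:
    def test_no_boundary_attackers_is_undefined(self):
        pop = two_cell_duel(gap=20.0)  # strains out of contact
        with pytest.raises(M.UndefinedMetricError):
            M.estimate_hit_probability(pop, needles_per_cell=50)

    def test_single_file_matches_independent_monte_carlo(self):
        """Attacker flanked by susceptibles: library estimate vs a
        Monte-Carlo oracle built from the per-cell needle API and the
        KKT distance oracle."""
        from t6sim.combat import construct_needle
        from conftest import oracle_segment_distance

        pop = single_file_chamber(3, alternating=True)
        pop.genotype[:] = np.array([1, 0, 1])  # susceptible-attacker-susceptible
        est = M.estimate_hit_probability(pop, needles_per_cell=4000, seed=1)

        rng = np.random.default_rng(99)
        cell = pop.cell(1)
        pa, pb = pop.endpoints()
        hits = 0
        n_mc = 20000
        for _ in range(n_mc):
            ndl = construct_needle(cell, rng)
            tip = ndl.origin + ndl.length * ndl.direction
            for j in (0, 2):
                dist, _, _ = oracle_segment_distance(ndl.origin, tip,
                                                     pa[j], pb[j])
                if dist <= pop.radius[j]:
                    hits += 1
                    break
        mc = hits / n_mc
        se = np.sqrt(mc * (1 - mc) / n_mc)
        assert est == pytest.approx(mc, abs=4 * se + 0.01)

    def test_prediction_formula(self):
        assert M.predict_kill_rate(1.0, 50.0, 0.2) == 0.0
        assert M.predict_kill_rate(0.0, 50.0, 0.2) == pytest.approx(10.0)
        assert M.predict_kill_rate(0.5, 50.0, 0.2) == pytest.approx(5.0)
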