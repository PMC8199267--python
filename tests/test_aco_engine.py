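"""Pheromone bookkeeping, sampling, local search and the colony loop."""

import numpy as np
import pytest
from scipy import stats

from antdock.aco_engine import (ACOParams, AntSolution, deposit_indicator,
                                init_pheromones, local_search, optimize,
                                resolve_defaults, sample_ant, select_interval,
                                update_pheromones)
from antdock.conformation import DofSpec, Partition
from antdock.errors import ConfigurationError, DomainError


def simple_spec(n_dofs=2, n_intervals=8, rotational=False):
    if rotational:
        bounds = [(0.0, 360.0)] * n_dofs
        parts = [Partition.regular(0.0, 360.0, n_intervals)] * n_dofs
    else:
        bounds = [(0.0, 8.0)] * n_dofs
        parts = [Partition.regular(0.0, 8.0, n_intervals)] * n_dofs
    return DofSpec(bounds=bounds, rotational=[rotational] * n_dofs,
                   partitions=parts)


class TestInitAndSelection:
    def test_initial_selection_is_uniform(self):
        ph = init_pheromones(simple_spec())
        for i in range(ph.spec.n):
            p = ph.probabilities(i)
            np.testing.assert_allclose(p, np.full(len(p), 1.0 / len(p)))

    def test_single_interval_probability_one(self):
        spec = simple_spec(n_dofs=1, n_intervals=1)
        ph = init_pheromones(spec)
        np.testing.assert_allclose(ph.probabilities(0), [1.0])

    def test_tau0_within_clamping_bounds(self):
        for n_intervals in (1, 4, 16, 360):
            ph = init_pheromones(simple_spec(n_intervals=n_intervals))
            for i in range(ph.spec.n):
                assert ph.tau_min[i] <= ph.tau[i][0] <= ph.tau_max[i]

    def test_degenerate_mass_selects_it(self):
        rng = np.random.default_rng(0)
        assert all(select_interval(np.array([3.0, 0.0, 0.0]), rng) == 1
                   for _ in range(100))

    def test_all_zero_row_rejected(self):
        with pytest.raises(DomainError):
            select_interval(np.zeros(4), np.random.default_rng(0))

    def test_uniform_row_chi_square(self):
        rng = np.random.default_rng(101)
        n = 8
        draws = np.array([select_interval(np.ones(n), rng)
                          for _ in range(100_000)])
        counts = np.bincount(draws, minlength=n + 1)[1:]
        assert stats.chisquare(counts).pvalue > 0.01

    def test_proportional_selection_frequencies(self):
        # tau = (1, 3) -> probabilities (0.25, 0.75) within 3 binomial SE
        rng = np.random.default_rng(77)
        n_draws = 100_000
        draws = np.array([select_interval(np.array([1.0, 3.0]), rng)
                          for _ in range(n_draws)])
        freq = np.mean(draws == 2)
        se = np.sqrt(0.25 * 0.75 / n_draws)
        assert abs(freq - 0.75) < 3 * se

    def test_normalization_exact(self):
        rng = np.random.default_rng(5)
        for _ in range(100):
            tau = rng.uniform(0.1, 10.0, size=12)
            assert np.sum(tau / tau.sum()) == pytest.approx(1.0, abs=1e-12)


class TestSampleAnt:
    def test_concentrated_matrix_confines_samples(self):
        spec = simple_spec()
        ph = init_pheromones(spec)
        for i in range(spec.n):
            ph.tau[i][:] = 0.0
            ph.tau[i][2] = 1.0  # interval 3 only
        rng = np.random.default_rng(1)
        for _ in range(100):
            x = sample_ant(ph, spec, rng)
            for i, p in enumerate(spec.partitions):
                assert p.lower(3) <= x[i] <= p.upper(3)

    def test_samples_respect_bounds(self):
        spec = simple_spec(rotational=True)
        ph = init_pheromones(spec)
        rng = np.random.default_rng(2)
        samples = np.array([sample_ant(ph, spec, rng) for _ in range(10_000)])
        assert samples.min() >= 0.0 and samples.max() <= 360.0

    def test_occupancy_matches_trail_probabilities(self):
        spec = simple_spec(n_dofs=1, n_intervals=4)
        ph = init_pheromones(spec)
        ph.tau[0][:] = np.array([1.0, 2.0, 3.0, 4.0])
        rng = np.random.default_rng(3)
        n_draws = 50_000
        cells = np.array([spec.cell_of(sample_ant(ph, spec, rng))[0]
                          for _ in range(n_draws)])
        expected = np.array([0.1, 0.2, 0.3, 0.4])
        freq = np.bincount(cells, minlength=5)[1:] / n_draws
        se = np.sqrt(expected * (1 - expected) / n_draws)
        assert np.all(np.abs(freq - expected) < 4 * se)

    def test_midpoint_mode_hits_cell_midpoints(self):
        spec = simple_spec(n_dofs=1, n_intervals=4)
        ph = init_pheromones(spec)
        rng = np.random.default_rng(4)
        mids = {spec.partitions[0].midpoint(ell) for ell in range(1, 5)}
        for _ in range(20):
            x = sample_ant(ph, spec, rng, representative="midpoint")
            assert float(x[0]) in mids


class TestLocalSearch:
    def test_convex_quadratic_converges(self):
        spec = simple_spec(n_dofs=3)
        c = np.array([3.0, 5.0, 2.5])
        f = lambda x: float(np.sum((x - c) ** 2))
        sol = local_search(c + 0.4, f, sigma=1.0, spec=spec, budget=400)
        np.testing.assert_allclose(sol.s, c, atol=1e-3)
        assert sol.f_s <= f(c + 0.4)

    def test_constant_objective_no_false_improvement(self):
        spec = simple_spec(n_dofs=2)
        sol = local_search(np.array([4.0, 4.0]), lambda x: 7.0, sigma=0.5,
                           spec=spec)
        assert sol.f_s == 7.0

    def test_matches_analytic_optimum_on_random_quadratics(self):
        rng = np.random.default_rng(21)
        spec = simple_spec(n_dofs=2)
        for _ in range(20):
            c = rng.uniform(1.0, 7.0, size=2)
            w = rng.uniform(0.5, 3.0, size=2)
            f = lambda x: float(np.sum(w * (x - c) ** 2))
            x0 = np.clip(c + rng.uniform(-0.5, 0.5, 2), 0, 8)
            sol = local_search(x0, f, sigma=1.0, spec=spec, budget=500)
            np.testing.assert_allclose(sol.s, c, atol=1e-3)

    def test_never_worse_than_start(self):
        rng = np.random.default_rng(22)
        spec = simple_spec(n_dofs=2, rotational=True)
        f = lambda x: float(np.sin(np.deg2rad(x[0])) * np.cos(np.deg2rad(x[1])))
        for _ in range(20):
            x0 = rng.uniform(0, 360, 2)
            sol = local_search(x0, f, sigma=0.3, spec=spec, budget=60)
            assert sol.f_s <= f(x0) + 1e-12
            assert np.all(sol.s >= 0) and np.all(sol.s <= 360)


class TestDepositIndicator:
    def test_own_interval_always_deposits(self):
        for rotational in (True, False):
            p = Partition.regular(0.0, 12.0, 12)
            for ell in range(1, 13):
                s = p.midpoint(ell)
                assert deposit_indicator(ell, s, p, rotational) == 1

    def test_far_value_no_deposit(self):
        p = Partition.regular(0.0, 12.0, 12)
        assert deposit_indicator(1, 7.5, p, False) == 0
        assert deposit_indicator(1, 6.5, p, True) == 0

    def test_window_table_exhaustive(self):
        """All (interval-of-s, ell) pairs on a 12-interval partition match an
        independently coded boundary-window membership, wrap-around included."""
        n = 12
        p_rot = Partition.regular(0.0, 360.0, n)
        p_lin = Partition.regular(0.0, 12.0, n)
        for ell in range(1, n + 1):
            for m in range(1, n + 1):
                # rotational window: intervals ell-2 .. ell+2 modulo n
                rot_window = {((ell - 1 + d) % n) + 1 for d in (-2, -1, 0, 1, 2)}
                s_rot = p_rot.midpoint(m)
                assert deposit_indicator(ell, s_rot, p_rot, True) == \
                    (1 if m in rot_window else 0)
                # non-rotational window: intervals ell-1 .. ell+1 clipped
                lin_window = {d for d in (ell - 1, ell, ell + 1)
                              if 1 <= d <= n}
                s_lin = p_lin.midpoint(m)
                assert deposit_indicator(ell, s_lin, p_lin, False) == \
                    (1 if m in lin_window else 0)


class TestUpdate:
    def toy(self):
        spec = DofSpec(
            bounds=[(0.0, 360.0), (0.0, 4.0)],
            rotational=[True, False],
            partitions=[Partition.regular(0.0, 360.0, 4),
                        Partition.regular(0.0, 4.0, 4)])
        return spec, init_pheromones(spec)

    def test_hand_computed_update(self):
        """rho=0.15, f(s)=-5, s=(10 deg, 3.5): expected trail values worked
        out by hand from the evaporation/deposit/clamp sequence."""
        spec, ph = self.toy()
        best = AntSolution(x=np.array([10.0, 3.5]), s=np.array([10.0, 3.5]),
                           f_s=-5.0)
        params = ACOParams(n_ants=1, rho=0.15, sigma=0.5, iterations=1)
        update_pheromones(ph, best, params)
        # dof 0 (rotational, 4 intervals): the +/-2-interval window wraps to
        # cover everything -> every trail gets 0.85 + 5 = 5.85
        np.testing.assert_allclose(ph.tau[0], [5.85] * 4, atol=1e-12)
        # dof 1: s in interval 4, window {3, 4}; others evaporate to 0.85 and
        # clamp up to tau_min = (5/0.15) / 8 = 4.1666...
        tau_max = 5.0 / 0.15
        tau_min = tau_max / 8.0
        np.testing.assert_allclose(ph.tau[1],
                                   [tau_min, tau_min, 5.85, 5.85], atol=1e-9)
        assert ph.t == 1

    def test_no_evaporation_no_deposit_is_identity(self):
        spec, ph = self.toy()
        before = [row.copy() for row in ph.tau]
        best = AntSolution(x=np.zeros(2), s=np.array([5.0, 1.0]), f_s=2.0)
        update_pheromones(ph, best, ACOParams(n_ants=1, rho=0.0, sigma=1.0,
                                              iterations=1))
        for row, ref in zip(ph.tau, before):
            np.testing.assert_allclose(row, ref)

    def test_full_evaporation_rests_at_tau_min(self):
        spec, ph = self.toy()
        best = AntSolution(x=np.zeros(2), s=np.array([5.0, 1.0]), f_s=0.5)
        update_pheromones(ph, best, ACOParams(n_ants=1, rho=1.0, sigma=1.0,
                                              iterations=1))
        for i, row in enumerate(ph.tau):
            np.testing.assert_allclose(row, np.full(len(row), ph.tau_min[i]))

    def test_clamping_never_violated_over_random_updates(self):
        spec, ph = self.toy()
        rng = np.random.default_rng(31)
        params = ACOParams(n_ants=1, rho=0.15, sigma=0.5, iterations=1)
        for _ in range(10_000):
            s = np.array([rng.uniform(0, 360), rng.uniform(0, 4)])
            best = AntSolution(x=s, s=s, f_s=float(rng.uniform(-50, 10)))
            update_pheromones(ph, best, params)
            for i, row in enumerate(ph.tau):
                assert np.all(row >= ph.tau_min[i] - 1e-12)
                assert np.all(row <= ph.tau_max[i] + 1e-12)
                assert np.isfinite(row).all()

    def test_probabilities_normalized_during_run(self):
        spec, ph = self.toy()
        rng = np.random.default_rng(32)
        params = ACOParams(n_ants=1, rho=0.2, sigma=0.5, iterations=1)
        for _ in range(50):
            s = np.array([rng.uniform(0, 360), rng.uniform(0, 4)])
            update_pheromones(ph, AntSolution(x=s, s=s,
                                              f_s=float(rng.uniform(-20, 0))),
                              params)
            for i in range(spec.n):
                assert ph.probabilities(i).sum() == pytest.approx(1.0,
                                                                  abs=1e-12)


class TestDefaults:
    @pytest.mark.parametrize("scoring,speed,ants,evap,sigma", [
        ("chemplp", 4, 20, 0.15, 0.25),
        ("chemplp", 2, 20, 0.20, 0.5),
        ("chemplp", 1, 20, 0.20, 1.25),
        ("plp", 4, 20, 0.2, 0.5),
        ("plp95", 4, 20, 0.2, 1.25),
    ])
    def test_defaults_table(self, scoring, speed, ants, evap, sigma):
        params = resolve_defaults(scoring, speed)
        assert params.n_ants == ants
        assert params.rho == evap
        assert params.sigma == sigma

    def test_unknown_combination(self):
        with pytest.raises(ConfigurationError):
            resolve_defaults("plp", 1)
        with pytest.raises(ConfigurationError):
            resolve_defaults("goldscore", 4)

    def test_iteration_budget_scales_with_speed(self):
        assert resolve_defaults("chemplp", 4).iterations == 25
        assert resolve_defaults("chemplp", 2).iterations == 50
        assert resolve_defaults("chemplp", 1).iterations == 100


def separable_basin_objective(spec, centers, depth=10.0, width=0.6):
    def f(x):
        return float(-depth * np.sum(
            np.exp(-0.5 * ((np.asarray(x) - centers) / width) ** 2)))
    return f


class TestOptimize:
    def test_best_so_far_trace_non_increasing(self):
        spec = simple_spec(n_dofs=2, n_intervals=8)
        f = separable_basin_objective(spec, np.array([2.5, 5.5]))
        for seed in range(5):
            result = optimize(f, spec, ACOParams(n_ants=5, rho=0.2, sigma=0.5,
                                                 iterations=20, seed=seed),
                              use_local_search=False, stagnation_limit=None)
            assert all(b <= a + 1e-12 for a, b in
                       zip(result.trace, result.trace[1:]))

    def test_bit_reproducible_from_seed(self):
        spec = simple_spec(n_dofs=2, n_intervals=8)
        f = separable_basin_objective(spec, np.array([2.5, 5.5]))
        params = ACOParams(n_ants=5, rho=0.2, sigma=0.5, iterations=15, seed=9)
        a = optimize(f, spec, params, use_local_search=True)
        b = optimize(f, spec, params, use_local_search=True)
        np.testing.assert_array_equal(a.best.s, b.best.s)
        assert a.best.f_s == b.best.f_s
        assert a.trace == b.trace

    def test_finds_discretized_optimum_two_dof(self):
        """With local search off, the colony recovers the brute-force best
        cell on a 2-dof landscape in >= 95/100 seeded runs."""
        spec = simple_spec(n_dofs=2, n_intervals=8)
        centers = np.array([2.5, 5.5])  # midpoints of cells (3, 6)
        f = separable_basin_objective(spec, centers)
        best_cell = min(
            ((i, j) for i in range(1, 9) for j in range(1, 9)),
            key=lambda c: f(np.array([spec.partitions[0].midpoint(c[0]),
                                      spec.partitions[1].midpoint(c[1])])))
        hits = 0
        for seed in range(100):
            result = optimize(f, spec,
                              ACOParams(n_ants=20, rho=0.2, sigma=0.5,
                                        iterations=50, seed=seed),
                              use_local_search=False, stagnation_limit=None)
            hits += spec.cell_of(result.best.s) == best_cell
        assert hits >= 95

    def test_basin_probability_mass_grows(self):
        """The selection probability of the basin interval is non-decreasing
        in expectation (sign test over 50 seeds)."""
        spec = simple_spec(n_dofs=1, n_intervals=8)
        centers = np.array([2.5])
        f = separable_basin_objective(spec, centers)
        basin_cell = 3
        gains = 0
        for seed in range(50):
            ph = init_pheromones(spec)
            rng = np.random.default_rng(seed)
            params = ACOParams(n_ants=10, rho=0.2, sigma=0.5, iterations=1)
            p_start = ph.probabilities(0)[basin_cell - 1]
            for t in range(15):
                best = None
                for a in range(10):
                    x = sample_ant(ph, spec, rng)
                    val = f(x)
                    if best is None or val < best.f_s:
                        best = AntSolution(x=x, s=x, f_s=val)
                update_pheromones(ph, best, params)
            p_end = ph.probabilities(0)[basin_cell - 1]
            gains += p_end > p_start
        assert stats.binomtest(gains, 50, 0.5,
                               alternative="greater").pvalue < 0.05

    def test_zero_volume_box_rejected(self):
        spec = simple_spec(n_dofs=1, n_intervals=1)
        spec.bounds[0] = (2.0, 2.0)
        with pytest.raises(ConfigurationError):
            optimize(lambda x: 0.0, spec,
                     ACOParams(n_ants=1, rho=0.1, sigma=0.5, iterations=1))


class TestRunAcoDocking:
    def test_same_seed_bit_reproducible(self, toy_complex):
        from antdock.aco_engine import run_aco
        from antdock.config import DockingScenario
        scen = DockingScenario(name="r", scoring_function="chemplp",
                               sphere=toy_complex.sphere, search_speed=4,
                               base_iterations=20, local_search=True,
                               local_search_budget=20,
                               angular_step=360.0, linear_step=1.0)
        a = run_aco(toy_complex.receptor, toy_complex.ligand, scen, seed=5)
        b = run_aco(toy_complex.receptor, toy_complex.ligand, scen, seed=5)
        np.testing.assert_array_equal(a.best.s, b.best.s)
        assert a.trace == b.trace
        assert a.n_evaluations == b.n_evaluations

    def test_speed_halves_evaluation_count(self, toy_complex):
        from antdock.aco_engine import run_aco
        from antdock.config import DockingScenario
        counts = {}
        for speed in (2, 4):
            scen = DockingScenario(name="s", scoring_function="chemplp",
                                   sphere=toy_complex.sphere,
                                   search_speed=speed, base_iterations=40,
                                   local_search=False, stagnation_limit=None,
                                   angular_step=360.0, linear_step=1.0)
            counts[speed] = run_aco(toy_complex.receptor, toy_complex.ligand,
                                    scen, seed=3).n_evaluations
        per_iteration = counts[4] / 10  # 10 iterations at speed 4
        assert abs(counts[2] - 2 * counts[4]) <= per_iteration
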