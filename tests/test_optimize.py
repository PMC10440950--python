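"""Residual minimization: recovery, determinism, stationarity, growth."""

import numpy as np
import pytest

from fraclag.manufactured import make_manufactured_problem
from fraclag.model import FractionalOrders, InitialState, default_parameters
from fraclag.optimize import (SolverConfig, SpectralProblem, grow_solve,
                              multistart_schedule, solve, stationarity_system)


@pytest.fixture(scope="module")
def manufactured():
    v = FractionalOrders(0.7, 0.9, 0.8, 1.0)
    return make_manufactured_problem(11, v, (2, 2, 3, 3))


def _recovery_starts(mp, prob, cfg, k=2):
    base = multistart_schedule(cfg.seed, k, cfg.bounds_for(prob.sizes), prob)
    return [(c, [np.array(b) for b in mp.exponents]) for c, _ in base]


class TestManufacturedRecovery:
    def test_exact_solution_recovered(self, manufactured):
        mp = manufactured
        prob = mp.spectral_problem()
        cfg = SolverConfig(optimize_exponents=False, multistarts=2, seed=0)
        res = solve(prob, cfg, starts=_recovery_starts(mp, prob, cfg))
        assert res.success
        assert res.objective < 1e-10
        for c, target in zip(res.coefficients, mp.target_coefficients):
            assert np.max(np.abs(c - target)) < 1e-6
        assert res.constraint_residual < 1e-12

    def test_exact_solution_is_stationary(self, manufactured):
        mp = manufactured
        prob = mp.spectral_problem()
        point = {"coefficients": [np.array(c) for c in mp.target_coefficients],
                 "exponents": [np.array(b) for b in mp.exponents],
                 "multipliers": np.zeros(4)}
        theta, gC, gB = stationarity_system(point, prob)
        assert np.max(np.abs(theta)) < 1e-12
        assert np.linalg.norm(np.concatenate([gC, gB])) < 1e-6


class TestStationaritySystem:
    def test_multiplier_block_equals_constraints(self, manufactured, rng):
        mp = manufactured
        prob = mp.spectral_problem()
        coeffs = [rng.normal(size=m + 1) for m in prob.sizes]
        point = {"coefficients": coeffs,
                 "exponents": [np.array(b) for b in mp.exponents],
                 "multipliers": rng.normal(size=4)}
        theta, _, _ = stationarity_system(point, prob)
        y0 = prob.init.as_array()
        expected = np.array([c.sum() - y0[i] for i, c in enumerate(coeffs)])
        assert np.array_equal(theta, expected)

    def test_agrees_with_central_differences(self, rng):
        v = FractionalOrders(0.7, 0.9, 0.8, 1.0)
        prob = SpectralProblem(default_parameters(), v,
                               InitialState(5, 0, 20, 200), 150.0,
                               (2, 2, 2, 2), node_count=16)
        coeffs = [rng.normal(size=3) * 0.3 for _ in range(4)]
        expos = [rng.uniform(0.0, 1.0, 2) for _ in range(4)]
        xi = rng.normal(size=4)
        point = {"coefficients": coeffs, "exponents": expos, "multipliers": xi}
        theta, gC, gB = stationarity_system(point, prob)

        from fraclag.optimize import _Packing, _ResidualModel
        frame = prob.frame()
        y0s = prob.init.as_array() / frame.state_scales
        pk = _Packing(prob.sizes, y0s, True, eliminate=False)
        model = _ResidualModel(prob.evaluator(), pk)

        def lag(cs, bs):
            q = model.objective(pk.pack(cs, bs))
            th = np.array([c.sum() - y0s[i] for i, c in enumerate(cs)])
            return q + xi @ th

        idx = 0
        for i, m in enumerate(prob.sizes):
            for a in range(m + 1):
                h = 1e-6 * max(1.0, abs(coeffs[i][a]))
                cp = [c.copy() for c in coeffs]
                cm = [c.copy() for c in coeffs]
                cp[i][a] += h
                cm[i][a] -= h
                fd = (lag(cp, expos) - lag(cm, expos)) / (2 * h)
                assert gC[idx] == pytest.approx(fd, rel=1e-5, abs=1e-7)
                idx += 1
        idx = 0
        for i, m in enumerate(prob.sizes):
            for b in range(m):
                h = 1e-6
                bp = [e.copy() for e in expos]
                bm = [e.copy() for e in expos]
                bp[i][b] += h
                bm[i][b] -= h
                fd = (lag(coeffs, bp) - lag(coeffs, bm)) / (2 * h)
                assert gB[idx] == pytest.approx(fd, rel=1e-5, abs=1e-7)
                idx += 1


class TestMultistartSchedule:
    def test_deterministic(self, manufactured):
        prob = manufactured.spectral_problem()
        cfg = SolverConfig()
        bounds = cfg.bounds_for(prob.sizes)
        s1 = multistart_schedule(3, 4, bounds, prob)
        s2 = multistart_schedule(3, 4, bounds, prob)
        for (c1, b1), (c2, b2) in zip(s1, s2):
            for a, b in zip(c1 + b1, c2 + b2):
                assert np.array_equal(a, b)

    def test_first_start_has_zero_exponents(self, manufactured):
        prob = manufactured.spectral_problem()
        cfg = SolverConfig()
        starts = multistart_schedule(0, 3, cfg.bounds_for(prob.sizes), prob)
        for b in starts[0][1]:
            # clipped into the validity window, so at most the tiny margin
            assert np.max(np.abs(b)) < 1e-8

    def test_seeds_change_later_starts(self, manufactured):
        prob = manufactured.spectral_problem()
        cfg = SolverConfig()
        bounds = cfg.bounds_for(prob.sizes)
        s0 = multistart_schedule(0, 3, bounds, prob)
        s1 = multistart_schedule(1, 3, bounds, prob)
        assert not all(
            np.array_equal(a, b)
            for (c0, b0), (c1, b1) in zip(s0[1:], s1[1:])
            for a, b in zip(b0, b1))


class TestSolveBehaviour:
    def test_bitwise_deterministic(self, manufactured):
        mp = manufactured
        prob = mp.spectral_problem()
        cfg = SolverConfig(optimize_exponents=False, multistarts=2, seed=5)
        starts = _recovery_starts(mp, prob, cfg)
        r1 = solve(prob, cfg, starts=starts)
        r2 = solve(prob, cfg, starts=starts)
        assert r1.objective == r2.objective
        for c1, c2 in zip(r1.coefficients, r2.coefficients):
            assert np.array_equal(c1, c2)

    def test_best_objective_monotone_in_multistarts(self):
        v = FractionalOrders.uniform(0.9)
        prob = SpectralProblem(default_parameters(), v,
                               InitialState(5, 0, 20, 200), 150.0,
                               (2, 2, 2, 2), node_count=24)
        vals = []
        for k in (1, 3):
            cfg = SolverConfig(multistarts=k, seed=7, max_iterations=60)
            vals.append(solve(prob, cfg).objective)
        assert vals[1] <= vals[0] + 1e-15

    def test_constraints_exact_in_elimination_mode(self, manufactured):
        mp = manufactured
        prob = mp.spectral_problem()
        cfg = SolverConfig(optimize_exponents=False, multistarts=1, seed=0)
        res = solve(prob, cfg, starts=_recovery_starts(mp, prob, cfg, k=1))
        y0 = prob.init.as_array()
        for i, c in enumerate(res.coefficients):
            assert c.sum() == pytest.approx(y0[i], abs=1e-13)

    def test_zero_start_recovers_trivial_active_macrophages(self):
        # with A0 = 0 the exact A-component is identically zero
        v = FractionalOrders.uniform(0.9)
        prob = SpectralProblem(default_parameters(), v,
                               InitialState(5, 0, 20, 200), 150.0,
                               (3, 3, 3, 3), node_count=32)
        cfg = SolverConfig(multistarts=2, seed=0, max_iterations=150)
        res = solve(prob, cfg)
        grid = np.linspace(0.0, 150.0, 101)
        a_traj = res.sample(grid)[:, 1]
        assert np.max(np.abs(a_traj)) < 1e-6   # A_scale = max(1, A0) = 1

    def test_kkt_mode_on_manufactured_problem(self):
        v = FractionalOrders(0.7, 0.9, 0.8, 1.0)
        mp = make_manufactured_problem(2, v, (1, 1, 2, 2))
        prob = mp.spectral_problem(node_count=24)
        cfg = SolverConfig(mode="kkt", optimize_exponents=False,
                           multistarts=1, seed=0, max_iterations=40)
        # warm solve inside kkt mode needs exponent-free starts; patch via
        # exponent bounds pinned at the manufactured values
        lo = [np.asarray(b) - 1e-9 for b in mp.exponents]
        hi = [np.asarray(b) + 1e-9 for b in mp.exponents]
        cfg = SolverConfig(mode="kkt", optimize_exponents=False,
                           multistarts=1, seed=0, max_iterations=40,
                           exponent_bounds=(lo, hi))
        res = solve(prob, cfg)
        assert res.multipliers is not None and res.multipliers.shape == (4,)
        assert res.constraint_residual < 1e-9
        assert res.objective < 1e-8


class TestNestedGrowth:
    def test_objective_non_increasing_with_basis_growth(self):
        v = FractionalOrders.uniform(1.0)
        prob = SpectralProblem(default_parameters(), v,
                               InitialState(5, 0, 20, 200), 150.0,
                               (5, 5, 5, 5), node_count=32)
        cfg = SolverConfig(multistarts=2, seed=0, max_iterations=120)
        res = grow_solve(prob, cfg, start_sizes=(2, 2, 2, 2))
        objs = [stage["objective"] for stage in res.diagnostics["growth"]]
        assert len(objs) == 4
        for a, b in zip(objs, objs[1:]):
            assert b <= a * (1 + 1e-12)
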