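"""Residual assembly, constraints, objective, Lagrangian, frame scaling."""

import numpy as np
import pytest

from fraclag.basis import BasisSpec
from fraclag.model import (FractionalOrders, InitialState, ModelParameters,
                           default_initial_state, default_parameters,
                           powered_parameters)
from fraclag.residual import (FrameScaling, NodeEvaluator, QuadratureRule,
                              SolutionAnsatz, constraints, lagrangian,
                              objective, residuals)


def small_ansatz(coeff_sets=None, betas=None, sizes=(2, 2, 2, 2)):
    bases = [BasisSpec(size=m,
                       exponents=np.zeros(m) if betas is None else betas[i])
             for i, m in enumerate(sizes)]
    if coeff_sets is None:
        coeff_sets = [np.zeros(m + 1) for m in sizes]
    return SolutionAnsatz.from_coefficients(coeff_sets, bases)


class TestQuadrature:
    def test_nodes_inside_open_interval(self):
        q = QuadratureRule.gauss_legendre(16, 150.0)
        assert q.node_count == 16
        assert np.all(q.weights > 0)
        assert np.all((q.nodes > 0) & (q.nodes <= 150.0))

    def test_polynomial_exactness(self):
        q = QuadratureRule.gauss_legendre(8, 2.0)
        # exact for degree <= 15: check t^7 over [0, 2]
        assert np.sum(q.weights * q.nodes ** 7) == pytest.approx(2.0 ** 8 / 8,
                                                                 rel=1e-13)

    def test_invalid_rules_rejected(self):
        with pytest.raises(ValueError):
            QuadratureRule(nodes=np.array([0.0, 1.0]),
                           weights=np.array([1.0, 1.0]), horizon=1.0)
        with pytest.raises(ValueError):
            QuadratureRule(nodes=np.array([0.5]),
                           weights=np.array([-1.0]), horizon=1.0)


class TestConstraints:
    def test_zero_coefficients(self):
        a = small_ansatz()
        theta = constraints(a, default_initial_state()).as_array()
        assert theta == pytest.approx([-5.0, 0.0, -20.0, -200.0])

    def test_ic_satisfying_ansatz(self):
        init = default_initial_state()
        coeffs = [np.array([x, 0.0, 0.0]) for x in init.as_array()]
        a = small_ansatz(coeffs)
        assert np.array_equal(constraints(a, init).as_array(), np.zeros(4))

    def test_matches_direct_series_evaluation(self, rng):
        coeffs = [rng.normal(size=3) for _ in range(4)]
        a = small_ansatz(coeffs, betas=[rng.uniform(0, 1, 2) for _ in range(4)])
        theta = constraints(a, default_initial_state()).as_array()
        direct = np.array([s(0.0) for s in a.series]) \
            - default_initial_state().as_array()
        assert theta == pytest.approx(direct, abs=1e-12)


class TestResiduals:
    def test_zero_ansatz_is_exact(self, params):
        v = FractionalOrders(0.7, 0.9, 0.8, 1.0)
        a = small_ansatz()
        for t in (0.5, 1.0, 10.0):
            assert np.array_equal(residuals(t, a, params, v).as_array(),
                                  np.zeros(4))

    def test_zero_active_macrophages_zero_second_residual(self, params, rng):
        v = FractionalOrders.uniform(0.9)
        coeffs = [rng.normal(size=3) for _ in range(4)]
        coeffs[1] = np.zeros(3)
        a = small_ansatz(coeffs)
        for t in (0.3, 2.0):
            assert residuals(t, a, params, v).r2 == 0.0

    def test_nonpositive_time_rejected(self, params, classical_orders):
        with pytest.raises(ValueError):
            residuals(0.0, small_ansatz(), params, classical_orders)

    def test_matches_symbolic_assembly(self, params, rng):
        """Term-by-term symbolic transcription of the residual equations."""
        import sympy as sp

        v = FractionalOrders(0.6, 0.8, 0.9, 1.0)
        sizes = (2, 2, 2, 2)
        betas = [rng.uniform(0.0, 1.0, 2) for _ in range(4)]
        coeffs = [rng.normal(size=3) for _ in range(4)]
        a = small_ansatz(coeffs, betas=betas, sizes=sizes)
        t0 = 1.0
        ours = residuals(t0, a, params, v).as_array()

        tsym = sp.Symbol("t", positive=True)
        orders = v.as_array()
        series_sym, deriv_sym = [], []
        for i in range(4):
            powers = [sp.Integer(0)] + [sp.Float(k + 1 + betas[i][k], 30)
                                        for k in range(2)]
            D = sp.Matrix([[1, 0, 0], [1, -1, 0],
                           [1, -2, sp.Rational(1, 2)]])
            phi = sp.Matrix([tsym ** p for p in powers])
            c = sp.Matrix([[sp.Float(x, 30) for x in coeffs[i]]])
            series_sym.append((c * D * phi)[0, 0])
            dphi = sp.Matrix([
                sp.Integer(0) if k == 0 else
                sp.gamma(powers[k] + 1) / sp.gamma(powers[k] + 1 - orders[i])
                * tsym ** (powers[k] - orders[i])
                for k in range(3)])
            deriv_sym.append((c * D * dphi)[0, 0])
        q = powered_parameters(params, v)
        T, A, M, W = series_sym
        f_sym = [
            q["d2"] * T * (1 - T / q["l2"]) - q["theta"] * T * A
            - q["alpha1"] * W * T,
            q["rho1"] * M * A - q["h2"] * A,
            q["d1"] * M * (1 - M / q["l1"]) - q["rho2"] * M * A - q["h1"] * M,
            q["d3"] * W * (1 - W / q["l3"]) - q["alpha2"] * W * T,
        ]
        oracle = np.array([
            float((deriv_sym[i] - f_sym[i]).subs(tsym, t0).evalf(30))
            for i in range(4)])
        assert ours == pytest.approx(oracle, rel=1e-10, abs=1e-12)


class TestObjective:
    def test_stationary_constant_ansatz_scores_zero(self, params):
        # a constant ansatz sitting on a coordinate equilibrium has zero
        # residual everywhere, hence zero objective
        v = FractionalOrders.uniform(1.0)
        q = powered_parameters(params, v)
        m_star = q["l1"] * (1.0 - q["h1"] / q["d1"])
        coeffs = [np.zeros(3), np.zeros(3),
                  np.array([m_star, 0, 0]), np.zeros(3)]
        a = small_ansatz(coeffs)
        rule = QuadratureRule.gauss_legendre(24, 5.0)
        assert objective(a, params, v, rule) == pytest.approx(0.0, abs=1e-12)

    def test_nonnegative(self, params, rng):
        v = FractionalOrders.uniform(0.8)
        coeffs = [rng.normal(size=3) * 10 for _ in range(4)]
        a = small_ansatz(coeffs)
        rule = QuadratureRule.gauss_legendre(16, 2.0)
        assert objective(a, params, v, rule) >= 0.0

    def test_polynomial_residual_integrates_exactly(self, rng):
        # with every rate zero the residual is just the series derivative,
        # a polynomial whose squared integral has a closed form
        p0 = ModelParameters(rho1=0, rho2=0, d1=0, d2=0, d3=0, alpha1=0,
                             alpha2=0, h1=0, h2=0, theta=0)
        v = FractionalOrders.uniform(1.0)
        coeffs = [rng.normal(size=3) for _ in range(4)]
        a = small_ansatz(coeffs)
        rule = QuadratureRule.gauss_legendre(16, 3.0)
        got = objective(a, p0, v, rule)
        total = 0.0
        for s in a.series:
            g = s.monomial_weights        # derivative: g1 + 2 g2 t
            poly = np.polynomial.Polynomial([g[1], 2 * g[2]]) ** 2
            total += poly.integ()(3.0)
        assert got == pytest.approx(total, rel=1e-10)

    def test_invariant_under_node_permutation(self, params, rng):
        v = FractionalOrders.uniform(0.9)
        coeffs = [rng.normal(size=3) for _ in range(4)]
        a = small_ansatz(coeffs)
        rule = QuadratureRule.gauss_legendre(12, 1.0)
        perm = rng.permutation(12)
        shuffled = QuadratureRule(nodes=rule.nodes[perm],
                                  weights=rule.weights[perm], horizon=1.0)
        assert objective(a, params, v, rule) == pytest.approx(
            objective(a, params, v, shuffled), rel=1e-12)

    def test_quadrature_refinement_converges(self, params, rng):
        # exponents 0.5 at order 0.5 keep every residual power mild, so the
        # integrand is smooth and the Gauss value has saturated by n = 48
        v = FractionalOrders.uniform(0.5)
        coeffs = [rng.normal(size=3) * 0.5 for _ in range(4)]
        betas = [np.full(2, 0.5) for _ in range(4)]
        a = small_ansatz(coeffs, betas=betas)
        vals = [objective(a, params, v, QuadratureRule.gauss_legendre(n, 1.0))
                for n in (48, 96)]
        assert abs(vals[1] - vals[0]) < 1e-8 * max(1.0, abs(vals[1]))


class TestLagrangian:
    def test_reduces_to_objective_without_multipliers(self, params, rng):
        v = FractionalOrders.uniform(0.8)
        coeffs = [rng.normal(size=3) for _ in range(4)]
        a = small_ansatz(coeffs)
        rule = QuadratureRule.gauss_legendre(8, 1.0)
        init = default_initial_state()
        assert lagrangian(a, np.zeros(4), params, v, rule, init) == \
            pytest.approx(objective(a, params, v, rule))

    def test_constraint_satisfying_point_is_multiplier_free(self, params, rng):
        v = FractionalOrders.uniform(0.8)
        init = InitialState(1.0, 0.5, 2.0, 3.0)
        coeffs = [np.array([x, 0.4, -0.4]) for x in init.as_array()]
        a = small_ansatz(coeffs)
        rule = QuadratureRule.gauss_legendre(8, 1.0)
        q0 = objective(a, params, v, rule)
        for xi in (np.ones(4), rng.normal(size=4) * 100):
            assert lagrangian(a, xi, params, v, rule, init) == \
                pytest.approx(q0)

    def test_linear_in_multipliers(self, params, rng):
        v = FractionalOrders.uniform(0.8)
        coeffs = [rng.normal(size=3) for _ in range(4)]
        a = small_ansatz(coeffs)
        rule = QuadratureRule.gauss_legendre(8, 1.0)
        init = default_initial_state()
        xi = rng.normal(size=4)
        q0 = objective(a, params, v, rule)
        j1 = lagrangian(a, xi, params, v, rule, init)
        j2 = lagrangian(a, 2 * xi, params, v, rule, init)
        assert j2 - q0 == pytest.approx(2 * (j1 - q0), rel=1e-10)

    def test_multiplier_gradient_is_constraint_vector(self, params, rng):
        v = FractionalOrders.uniform(0.8)
        coeffs = [rng.normal(size=3) for _ in range(4)]
        a = small_ansatz(coeffs)
        rule = QuadratureRule.gauss_legendre(8, 1.0)
        init = default_initial_state()
        xi = rng.normal(size=4)
        theta = constraints(a, init).as_array()
        h = 1e-4
        for i in range(4):
            xp, xm = xi.copy(), xi.copy()
            xp[i] += h
            xm[i] -= h
            fd = (lagrangian(a, xp, params, v, rule, init)
                  - lagrangian(a, xm, params, v, rule, init)) / (2 * h)
            assert fd == pytest.approx(theta[i], rel=1e-9, abs=1e-9)


class TestFrameScaling:
    def test_time_scaling_consistency(self, params, rng):
        """Normalized-frame residuals x chain factors == literal residuals."""
        v = FractionalOrders(0.6, 0.8, 0.9, 1.0)
        init = default_initial_state()
        horizon = 150.0
        sizes = (2, 2, 2, 2)
        betas = [rng.uniform(0.0, 1.0, 2) for _ in range(4)]
        coeffs = [rng.normal(size=3) * 0.3 for _ in range(4)]
        bases = [BasisSpec(size=2, exponents=b) for b in betas]

        frame = FrameScaling.normalized(horizon, init, params)
        rule = QuadratureRule.gauss_legendre(8, 1.0)
        ev = NodeEvaluator(params, v, sizes, frame, rule)
        r_frame = ev.residual_nodes(coeffs, bases)
        r_literal_pred = r_frame * ev.literal_residual_factors()[None, :]

        # literal evaluation: the same scaled function expressed in days
        scaled = [c * frame.state_scales[i] for i, c in enumerate(coeffs)]
        literal = _rescaled_ansatz(scaled, bases, horizon)
        for k, tau in enumerate(rule.nodes):
            r_lit = residuals(tau * horizon, literal, params, v).as_array()
            scale = np.maximum(np.abs(r_lit), 1e-6)
            assert np.max(np.abs(r_lit - r_literal_pred[k]) / scale) < 1e-9


def _rescaled_ansatz(scaled_coeffs, bases, horizon):
    """Express y(t/zeta) in physical time by absorbing zeta into coefficients.

    For a monomial t^p the rescaling multiplies the monomial weight by
    zeta^{-p}; push that diagonal through the coefficient matrix.
    """
    from fraclag.basis import build_coefficient_matrix

    new_coeffs = []
    for c, b in zip(scaled_coeffs, bases):
        D = build_coefficient_matrix(b.size).entries
        g = D.T @ c
        g_scaled = g * horizon ** (-b.powers)
        c_new = np.linalg.solve(D.T, g_scaled)
        new_coeffs.append(c_new)
    return SolutionAnsatz.from_coefficients(new_coeffs, bases)
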