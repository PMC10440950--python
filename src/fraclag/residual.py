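"""Residual functions, initial-condition constraints, objective and Lagrangian.

Substituting the four GLP ansatz series into the model equations leaves a
defect (residual) per equation,

    R_i(t) = D^{v_i} x_i(t) - f_i(x(t)),

whose squared 2-norm integrated over the horizon,

    Q = int_0^zeta  sum_i R_i(t)^2  dt,

is the objective minimized over coefficients and exponents.  The initial
conditions enter as linear constraints Theta_i = x_i(0) - x_i0 (the
monomial vector collapses to [1, 0, ..., 0] at t = 0, so x_i(0) is just the
sum of the Laguerre coefficients).  The Lagrangian J = Q + xi . Theta
carries one multiplier per constraint.

Two coordinate frames are supported through :class:`FrameScaling`:

* the literal frame — states in cells, time in days on (0, zeta];
* a normalized frame — time tau = t/zeta on (0, 1] with the Caputo
  chain-rule factor zeta^{-v_i}, states divided by per-state scales, and
  each residual divided by (scale_i * zeta^{-v_i}).

The literal frame reproduces the textbook objective; the normalized frame
is what makes horizons of 150 days and states of 1e7 cells numerically
workable, and is the optimizer default.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .basis import ApproximantSeries, BasisSpec, build_coefficient_matrix
from .caputo import caputo_derivative_series, operational_diagonal
from .model import FractionalOrders, InitialState, ModelParameters, powered_parameters

__all__ = [
    "QuadratureRule",
    "SolutionAnsatz",
    "ResidualVector",
    "ConstraintVector",
    "ObjectiveState",
    "FrameScaling",
    "NodeEvaluator",
    "residuals",
    "constraints",
    "objective",
    "lagrangian",
]

STATE_NAMES = ("T", "A", "M", "W")


@dataclass(frozen=True)
class QuadratureRule:
    """Positive-weight quadrature with nodes strictly inside (0, horizon]."""

    nodes: np.ndarray
    weights: np.ndarray
    horizon: float

    def __post_init__(self) -> None:
        nodes = np.asarray(self.nodes, dtype=float)
        weights = np.asarray(self.weights, dtype=float)
        if nodes.shape != weights.shape or nodes.ndim != 1:
            raise ValueError("nodes and weights must be matching 1-d arrays")
        if np.any(weights <= 0):
            raise ValueError("quadrature weights must be positive")
        if np.any(nodes <= 0) or np.any(nodes > self.horizon):
            raise ValueError("nodes must lie strictly inside (0, horizon]")
        object.__setattr__(self, "nodes", nodes)
        object.__setattr__(self, "weights", weights)

    @property
    def node_count(self) -> int:
        return self.nodes.size

    @classmethod
    def gauss_legendre(cls, n: int, horizon: float) -> "QuadratureRule":
        """Gauss-Legendre rule mapped from [-1, 1] to (0, horizon].

        Gauss nodes avoid both endpoints, in particular t = 0 where the
        operational form of the Caputo derivative carries a t^{-v} factor.
        """
        if n < 1:
            raise ValueError("node count must be >= 1")
        if horizon <= 0:
            raise ValueError("horizon must be positive")
        x, w = np.polynomial.legendre.leggauss(n)
        nodes = 0.5 * horizon * (x + 1.0)
        weights = 0.5 * horizon * w
        return cls(nodes=nodes, weights=weights, horizon=float(horizon))


@dataclass(frozen=True)
class SolutionAnsatz:
    """Four GLP series, one per state (T, A, M, W)."""

    series: tuple

    def __post_init__(self) -> None:
        if len(self.series) != 4:
            raise ValueError("an ansatz carries exactly four series")

    @classmethod
    def from_coefficients(cls, coefficient_sets, bases) -> "SolutionAnsatz":
        return cls(tuple(
            ApproximantSeries.from_coefficients(c, b)
            for c, b in zip(coefficient_sets, bases)
        ))

    def value(self, t: float) -> np.ndarray:
        return np.array([s(t) for s in self.series])

    def value_at_zero(self) -> np.ndarray:
        """x(0) by the closed linear form: the coefficient sums."""
        return np.array([float(np.sum(s.coefficients)) for s in self.series])

    @property
    def sizes(self) -> tuple:
        return tuple(s.basis.size for s in self.series)


@dataclass(frozen=True)
class ResidualVector:
    """The four equation defects at one time point (cells day^-v each)."""

    r1: float
    r2: float
    r3: float
    r4: float
    eval_time: float

    def as_array(self) -> np.ndarray:
        return np.array([self.r1, self.r2, self.r3, self.r4])


@dataclass(frozen=True)
class ConstraintVector:
    """Initial-condition defects Theta_1..Theta_4 (cells)."""

    theta1: float
    theta2: float
    theta3: float
    theta4: float

    def as_array(self) -> np.ndarray:
        return np.array([self.theta1, self.theta2, self.theta3, self.theta4])


@dataclass(frozen=True)
class ObjectiveState:
    """Objective Q, Lagrangian J and the multipliers xi that link them."""

    Q: float
    J: float
    multipliers: np.ndarray

    def __post_init__(self) -> None:
        if self.Q < 0:
            raise ValueError("objective must be nonnegative")


def residuals(t: float, a: SolutionAnsatz, p: ModelParameters,
              v: FractionalOrders) -> ResidualVector:
    """Literal residual vector at t > 0: Caputo derivative minus model rate."""
    t = float(t)
    if t <= 0:
        raise ValueError("residuals are evaluated at t > 0")
    orders = v.as_array()
    deriv = np.array([
        caputo_derivative_series(s, orders[i], t)
        for i, s in enumerate(a.series)
    ])
    x = a.value(t)
    q = powered_parameters(p, v)
    f = np.array([
        q["d2"] * x[0] * (1.0 - x[0] / q["l2"]) - q["theta"] * x[0] * x[1]
        - q["alpha1"] * x[3] * x[0],
        q["rho1"] * x[2] * x[1] - q["h2"] * x[1],
        q["d1"] * x[2] * (1.0 - x[2] / q["l1"]) - q["rho2"] * x[2] * x[1]
        - q["h1"] * x[2],
        q["d3"] * x[3] * (1.0 - x[3] / q["l3"]) - q["alpha2"] * x[3] * x[0],
    ])
    r = deriv - f
    return ResidualVector(r[0], r[1], r[2], r[3], eval_time=t)


def constraints(a: SolutionAnsatz, init: InitialState) -> ConstraintVector:
    """Theta_i = series_i(0) - x_i0, via the closed linear form."""
    theta = a.value_at_zero() - init.as_array()
    return ConstraintVector(*theta)


def objective(a: SolutionAnsatz, p: ModelParameters, v: FractionalOrders,
              q: QuadratureRule) -> float:
    """Quadrature approximation of int_0^zeta sum_i R_i(t)^2 dt."""
    total = 0.0
    for t, w in zip(q.nodes, q.weights):
        r = residuals(t, a, p, v).as_array()
        total += w * float(np.dot(r, r))
    return total


def lagrangian(a: SolutionAnsatz, xi, p: ModelParameters, v: FractionalOrders,
               q: QuadratureRule, init: InitialState) -> float:
    """J = Q + xi . Theta with one multiplier per initial condition."""
    xi = np.asarray(xi, dtype=float)
    theta = constraints(a, init).as_array()
    return objective(a, p, v, q) + float(np.dot(xi, theta))


# ---------------------------------------------------------------------------
# Scaled frames and fast node-wise evaluation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FrameScaling:
    """Coordinate frame for the optimization: time and state scalings.

    The ansatz argument runs over (0, domain_length]; physical time is
    t = (horizon/domain_length) * tau.  States are series values times
    ``state_scales``; residuals in this frame are the literal residuals
    divided by (state_scale_i * stretch^{-v_i}) where stretch is the time
    dilation factor.
    """

    horizon: float
    state_scales: np.ndarray
    domain_length: float = 1.0

    def __post_init__(self) -> None:
        s = np.asarray(self.state_scales, dtype=float)
        if s.shape != (4,) or np.any(s <= 0):
            raise ValueError("state_scales must be four positive reals")
        object.__setattr__(self, "state_scales", s)
        if self.horizon <= 0 or self.domain_length <= 0:
            raise ValueError("horizon and domain_length must be positive")

    @property
    def stretch(self) -> float:
        """Time dilation: physical days per unit of ansatz time."""
        return self.horizon / self.domain_length

    @classmethod
    def normalized(cls, horizon: float, init: InitialState,
                   p: ModelParameters) -> "FrameScaling":
        """Unit ansatz time; states scaled by (l2, max(1, A0), l1, l3)."""
        scales = np.array([p.l2, max(1.0, init.A0), p.l1, p.l3])
        return cls(horizon=horizon, state_scales=scales, domain_length=1.0)

    @classmethod
    def literal(cls, horizon: float) -> "FrameScaling":
        """No scaling: ansatz time is physical time, states in cells."""
        return cls(horizon=horizon, state_scales=np.ones(4),
                   domain_length=horizon)


class NodeEvaluator:
    """Vectorized residual evaluation at fixed quadrature nodes.

    Precomputes everything that does not depend on the exponents; the
    monomial and Caputo-derivative tables are rebuilt whenever new exponent
    vectors are supplied.  Works in an arbitrary :class:`FrameScaling`, and
    supports an additive forcing term per equation (used by manufactured
    problems).
    """

    def __init__(self, p: ModelParameters, v: FractionalOrders,
                 sizes, frame: FrameScaling, rule: QuadratureRule,
                 forcing=None):
        if abs(rule.horizon - frame.domain_length) > 1e-12 * max(1.0, frame.domain_length):
            raise ValueError("quadrature rule must cover (0, domain_length]")
        self.params = p
        self.orders = v.as_array()
        self.sizes = tuple(int(m) for m in sizes)
        self.frame = frame
        self.rule = rule
        self.powered = powered_parameters(p, v)
        self.coeff_matrices = [build_coefficient_matrix(m) for m in self.sizes]
        self.chain = frame.stretch ** self.orders          # zeta^{v_i} factors
        # forcing: (n_nodes, 4) array of g_i(tau) in frame units, or None
        self.forcing = None if forcing is None else np.asarray(forcing, dtype=float)

    # -- exponent-dependent tables ------------------------------------------

    def tables(self, bases) -> tuple:
        """(phi, dphi) per state: monomials and their Caputo derivatives.

        phi[i] has shape (n_nodes, m_i + 1); dphi[i] likewise, with the
        t^{-v} operational rule folded in (column 0 identically zero).
        """
        tau = self.rule.nodes
        phi, dphi = [], []
        for i, spec in enumerate(bases):
            pwr = spec.powers
            P = tau[:, None] ** pwr[None, :]
            diag = operational_diagonal(spec, self.orders[i])
            dP = np.zeros_like(P)
            if spec.size > 0:
                dP[:, 1:] = diag.factors[1:] * tau[:, None] ** (pwr[1:] - self.orders[i])
            phi.append(P)
            dphi.append(dP)
        return phi, dphi

    # -- core evaluation -----------------------------------------------------

    def state_nodes(self, coeff_sets, bases, tables=None) -> np.ndarray:
        """Series values y_i(tau_k): shape (n_nodes, 4)."""
        phi, _ = tables if tables is not None else self.tables(bases)
        cols = []
        for i in range(4):
            g = self.coeff_matrices[i].entries.T @ np.asarray(coeff_sets[i], dtype=float)
            cols.append(phi[i] @ g)
        return np.stack(cols, axis=1)

    def model_rate(self, y: np.ndarray) -> np.ndarray:
        """Frame-scaled model rate at node states y (n_nodes, 4)."""
        s = self.frame.state_scales
        x = y * s[None, :]
        q = self.powered
        with np.errstate(over="ignore", invalid="ignore"):
            f = np.stack([
                q["d2"] * x[:, 0] * (1.0 - x[:, 0] / q["l2"])
                - q["theta"] * x[:, 0] * x[:, 1] - q["alpha1"] * x[:, 3] * x[:, 0],
                q["rho1"] * x[:, 2] * x[:, 1] - q["h2"] * x[:, 1],
                q["d1"] * x[:, 2] * (1.0 - x[:, 2] / q["l1"])
                - q["rho2"] * x[:, 2] * x[:, 1] - q["h1"] * x[:, 2],
                q["d3"] * x[:, 3] * (1.0 - x[:, 3] / q["l3"])
                - q["alpha2"] * x[:, 3] * x[:, 0],
            ], axis=1)
        return f * (self.chain / s)[None, :]

    def rate_jacobian(self, y: np.ndarray) -> np.ndarray:
        """d(model_rate_j)/d(y_i) at each node: shape (n_nodes, 4, 4)."""
        s = self.frame.state_scales
        x = y * s[None, :]
        q = self.powered
        n = y.shape[0]
        J = np.zeros((n, 4, 4))
        J[:, 0, 0] = q["d2"] * (1.0 - 2.0 * x[:, 0] / q["l2"]) \
            - q["theta"] * x[:, 1] - q["alpha1"] * x[:, 3]
        J[:, 0, 1] = -q["theta"] * x[:, 0]
        J[:, 0, 3] = -q["alpha1"] * x[:, 0]
        J[:, 1, 1] = q["rho1"] * x[:, 2] - q["h2"]
        J[:, 1, 2] = q["rho1"] * x[:, 1]
        J[:, 2, 1] = -q["rho2"] * x[:, 2]
        J[:, 2, 2] = q["d1"] * (1.0 - 2.0 * x[:, 2] / q["l1"]) \
            - q["rho2"] * x[:, 1] - q["h1"]
        J[:, 3, 0] = -q["alpha2"] * x[:, 3]
        J[:, 3, 3] = q["d3"] * (1.0 - 2.0 * x[:, 3] / q["l3"]) \
            - q["alpha2"] * x[:, 0]
        # chain and scale factors: residual_j is divided by s_j, state i
        # perturbations are multiplied by s_i.
        factor = self.chain[None, :, None] * (s[None, None, :] / s[None, :, None])
        return J * factor

    def residual_nodes(self, coeff_sets, bases, tables=None) -> np.ndarray:
        """Frame residuals r_i(tau_k): shape (n_nodes, 4)."""
        tabs = tables if tables is not None else self.tables(bases)
        phi, dphi = tabs
        y = self.state_nodes(coeff_sets, bases, tabs)
        dcols = []
        for i in range(4):
            g = self.coeff_matrices[i].entries.T @ np.asarray(coeff_sets[i], dtype=float)
            dcols.append(dphi[i] @ g)
        r = np.stack(dcols, axis=1) - self.model_rate(y)
        if self.forcing is not None:
            r = r - self.forcing
        return r

    def objective_value(self, coeff_sets, bases) -> float:
        r = self.residual_nodes(coeff_sets, bases)
        return float(np.sum(self.rule.weights[:, None] * r * r))

    # -- frame conversions ----------------------------------------------------

    def scaled_initial_values(self, init: InitialState) -> np.ndarray:
        return init.as_array() / self.frame.state_scales

    def to_physical_time(self, tau) -> np.ndarray:
        return np.asarray(tau, dtype=float) * self.frame.stretch

    def literal_residual_factors(self) -> np.ndarray:
        """Multiply frame residuals by these to recover cells day^-v units."""
        return self.frame.state_scales * self.frame.stretch ** (-self.orders)
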