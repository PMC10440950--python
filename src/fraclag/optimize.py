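"""Residual-norm minimization over GLP coefficients and exponents.

The objective Q is a positive-weight quadrature sum of squared residuals,
so the natural inner solver is bound-constrained nonlinear least squares on
the stacked node residuals sqrt(w_k) * r_j(tau_k), with analytic Jacobians.
Two constraint-handling modes are provided:

* ``eliminate-ic`` (default) — the initial-condition constraints are linear
  in the coefficients (the series value at 0 is the plain coefficient sum),
  so one coefficient per state is eliminated and the constraints hold
  exactly by construction;
* ``kkt`` — the full Lagrangian stationarity system (constraints, coefficient
  gradient, exponent gradient) is solved by damped Newton with line search,
  mirroring the multiplier formulation literally.

Initialization is a deterministic seeded multistart: the first start is the
all-zero-exponent basis with coefficients from a linear least-squares fit to
a coarse predictor-corrector reference trajectory; later starts draw
exponents uniformly within bounds (coefficients refit linearly).  Runs are
reproducible bit-for-bit given (config, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import least_squares
from scipy.special import digamma

from .basis import BasisSpec, EXPONENT_MARGIN, build_coefficient_matrix
from .model import FractionalOrders, InitialState, ModelParameters
from .reference import StateTrajectory, abm_solve
from .residual import FrameScaling, NodeEvaluator, QuadratureRule

__all__ = [
    "SolverConfig",
    "SpectralProblem",
    "SolveResult",
    "default_exponent_bounds",
    "multistart_schedule",
    "stationarity_system",
    "solve",
    "grow_solve",
]


def default_exponent_bounds(sizes, upper: float = 2.0):
    """Per-state exponent windows: beta_i in [-min(i - margin, 0.9), upper]."""
    lo, hi = [], []
    for m in sizes:
        idx = np.arange(1, m + 1, dtype=float)
        lo.append(-np.minimum(idx - EXPONENT_MARGIN, 0.9))
        hi.append(np.full(m, float(upper)))
    return lo, hi


@dataclass(frozen=True)
class SolverConfig:
    """Optimizer settings (all reproducibility-relevant knobs live here)."""

    mode: str = "eliminate-ic"
    multistarts: int = 8
    seed: int = 0
    exponent_upper: float = 2.0
    exponent_bounds: tuple | None = None     # overrides exponent_upper
    optimize_exponents: bool = True
    gradient_tol: float = 1e-10
    constraint_tol: float = 1e-12
    max_iterations: int = 500
    reference_steps: int = 800

    def __post_init__(self) -> None:
        if self.mode not in ("eliminate-ic", "kkt"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.multistarts < 1:
            raise ValueError("multistarts must be >= 1")
        if min(self.gradient_tol, self.constraint_tol) <= 0:
            raise ValueError("tolerances must be positive")

    def bounds_for(self, sizes):
        if self.exponent_bounds is not None:
            return self.exponent_bounds
        return default_exponent_bounds(sizes, upper=self.exponent_upper)


@dataclass(frozen=True)
class SpectralProblem:
    """A residual-minimization problem: model + ansatz sizes + frame."""

    params: ModelParameters
    orders: FractionalOrders
    init: InitialState
    horizon: float
    sizes: tuple
    node_count: int = 64
    normalized: bool = True
    forcing = None                     # callable tau -> (4,) in frame units

    def __init__(self, params, orders, init, horizon, sizes,
                 node_count=64, normalized=True, forcing=None):
        object.__setattr__(self, "params", params)
        object.__setattr__(self, "orders", orders)
        object.__setattr__(self, "init", init)
        object.__setattr__(self, "horizon", float(horizon))
        object.__setattr__(self, "sizes", tuple(int(m) for m in sizes))
        object.__setattr__(self, "node_count", int(node_count))
        object.__setattr__(self, "normalized", bool(normalized))
        object.__setattr__(self, "forcing", forcing)
        if self.horizon <= 0:
            raise ValueError("horizon must be positive")
        if any(m < 1 for m in self.sizes):
            raise ValueError("every basis size must be >= 1")

    def frame(self) -> FrameScaling:
        if self.normalized:
            return FrameScaling.normalized(self.horizon, self.init, self.params)
        return FrameScaling.literal(self.horizon)

    def evaluator(self) -> NodeEvaluator:
        frame = self.frame()
        rule = QuadratureRule.gauss_legendre(self.node_count, frame.domain_length)
        forcing = None
        if self.forcing is not None:
            forcing = np.stack([np.asarray(self.forcing(t), dtype=float)
                                for t in rule.nodes])
        return NodeEvaluator(self.params, self.orders, self.sizes,
                             frame, rule, forcing=forcing)

    def frame_rhs(self):
        """Right-hand side of the frame-scaled system (for the reference run)."""
        frame = self.frame()
        rule1 = QuadratureRule.gauss_legendre(1, frame.domain_length)
        ev = NodeEvaluator(self.params, self.orders, self.sizes, frame, rule1)

        def rhs(t, y):
            f = ev.model_rate(np.asarray(y, dtype=float)[None, :])[0]
            if self.forcing is not None:
                f = f + np.asarray(self.forcing(max(t, 1e-12)), dtype=float)
            return f
        return rhs

    def reference_trajectory(self, steps: int = 800) -> StateTrajectory:
        """Coarse predictor-corrector run in frame coordinates."""
        frame = self.frame()
        y0 = self.init.as_array() / frame.state_scales
        return abm_solve(self.frame_rhs(), self.orders, y0,
                         frame.domain_length, N=steps)


@dataclass
class SolveResult:
    """Outcome of a residual-minimization run."""

    coefficients: list            # four arrays, length m_i + 1 (frame units)
    exponents: list               # four arrays, length m_i
    multipliers: np.ndarray | None
    objective: float              # frame objective Q*
    literal_objective: float      # same residuals in cells/day units
    constraint_residual: float
    success: bool
    message: str
    diagnostics: dict
    problem: SpectralProblem

    def bases(self):
        return [BasisSpec(size=len(b), exponents=b) for b in self.exponents]

    def sample(self, t) -> np.ndarray:
        """Physical-state trajectory at physical times t: shape (n, 4)."""
        frame = self.problem.frame()
        tau = np.atleast_1d(np.asarray(t, dtype=float)) / frame.stretch
        if np.any(tau < 0) or np.any(tau > frame.domain_length * (1 + 1e-12)):
            raise ValueError("sample times must lie within [0, horizon]")
        bases = self.bases()
        mats = [build_coefficient_matrix(b.size) for b in bases]
        out = np.empty((tau.size, 4))
        for i in range(4):
            g = mats[i].entries.T @ self.coefficients[i]
            powers = bases[i].powers
            P = np.zeros((tau.size, powers.size))
            P[:, 0] = 1.0
            pos = tau > 0
            P[pos, 1:] = tau[pos, None] ** powers[None, 1:]
            out[:, i] = P @ g
        return out * frame.state_scales[None, :]


# ---------------------------------------------------------------------------
# Packing and derivatives
# ---------------------------------------------------------------------------

class _Packing:
    """Maps the flat optimization vector to coefficient/exponent sets.

    Layout: [free coefficients per state] then [exponents per state] (the
    latter only when exponents are optimized).  In eliminate-ic mode the
    leading coefficient of each state is dependent: c_0 = y_i(0) - sum(rest).
    """

    def __init__(self, sizes, y0_scaled, optimize_exponents: bool,
                 eliminate: bool):
        self.sizes = tuple(sizes)
        self.y0 = np.asarray(y0_scaled, dtype=float)
        self.opt_exp = optimize_exponents
        self.eliminate = eliminate
        self.n_coeff = sum(m if eliminate else m + 1 for m in sizes)
        self.n_exp = sum(sizes) if optimize_exponents else 0
        self.size = self.n_coeff + self.n_exp

    def unpack(self, x, fixed_exponents=None):
        coeffs, expos = [], []
        pos = 0
        for i, m in enumerate(self.sizes):
            if self.eliminate:
                rest = x[pos:pos + m]
                c = np.concatenate(([self.y0[i] - rest.sum()], rest))
                pos += m
            else:
                c = np.array(x[pos:pos + m + 1])
                pos += m + 1
            coeffs.append(c)
        if self.opt_exp:
            for m in self.sizes:
                expos.append(np.array(x[pos:pos + m]))
                pos += m
        else:
            expos = [np.array(b, dtype=float) for b in fixed_exponents]
        return coeffs, expos

    def pack(self, coeffs, expos):
        parts = []
        for i, c in enumerate(coeffs):
            parts.append(c[1:] if self.eliminate else c)
        if self.opt_exp:
            parts.extend(expos)
        return np.concatenate(parts)


def _clip_exponents(expos, bounds, sizes):
    lo, hi = bounds
    return [np.clip(np.asarray(b, dtype=float), lo[i] + 1e-9, hi[i] - 1e-9)
            for i, b in enumerate(expos)]


class _ResidualModel:
    """Stacked weighted residuals and their analytic Jacobian."""

    def __init__(self, ev: NodeEvaluator, packing: _Packing,
                 fixed_exponents=None):
        self.ev = ev
        self.packing = packing
        self.fixed_exponents = fixed_exponents
        self.sqrt_w = np.sqrt(ev.rule.weights)

    def _bases(self, expos):
        return [BasisSpec(size=m, exponents=b)
                for m, b in zip(self.packing.sizes, expos)]

    def residuals(self, x):
        coeffs, expos = self.packing.unpack(x, self.fixed_exponents)
        bases = self._bases(expos)
        r = self.ev.residual_nodes(coeffs, bases)
        return (self.sqrt_w[:, None] * r).ravel()

    def jacobian(self, x):
        ev = self.ev
        pk = self.packing
        coeffs, expos = pk.unpack(x, self.fixed_exponents)
        bases = self._bases(expos)
        tabs = ev.tables(bases)
        phi, dphi = tabs
        tau = ev.rule.nodes
        n = tau.size
        y = ev.state_nodes(coeffs, bases, tabs)
        Jrate = ev.rate_jacobian(y)                 # (n, 4, 4): d f_j / d y_i
        ln_tau = np.log(tau)

        cols = []
        # coefficient columns
        for i, m in enumerate(pk.sizes):
            D = ev.coeff_matrices[i].entries
            a_range = range(1, m + 1) if pk.eliminate else range(0, m + 1)
            for a in a_range:
                gcol = D[a].copy()
                if pk.eliminate:
                    gcol = gcol - D[0]              # c_0 = y0 - sum(rest)
                dy = phi[i] @ gcol                  # d y_i / d c_a at nodes
                dD = dphi[i] @ gcol                 # d (D^v y_i) / d c_a
                block = np.zeros((n, 4))
                block[:, i] += dD
                block -= Jrate[:, :, i] * dy[:, None]
                cols.append(block)
        # exponent columns
        if pk.opt_exp:
            for i, m in enumerate(pk.sizes):
                D = ev.coeff_matrices[i].entries
                g = D.T @ coeffs[i]
                vi = ev.orders[i]
                for b in range(1, m + 1):
                    beta = expos[i][b - 1]
                    psi_diff = digamma(b + 1.0 + beta) - digamma(b + 1.0 - vi + beta)
                    dy = g[b] * ln_tau * phi[i][:, b]
                    dD = g[b] * (psi_diff + ln_tau) * dphi[i][:, b]
                    block = np.zeros((n, 4))
                    block[:, i] += dD
                    block -= Jrate[:, :, i] * dy[:, None]
                    cols.append(block)
        J = np.stack([(self.sqrt_w[:, None] * c).ravel() for c in cols], axis=1)
        return J

    def objective(self, x) -> float:
        r = self.residuals(x)
        return float(r @ r)

    def gradient(self, x) -> np.ndarray:
        r = self.residuals(x)
        return 2.0 * (self.jacobian(x).T @ r)


# ---------------------------------------------------------------------------
# Multistart schedule
# ---------------------------------------------------------------------------

def _linear_coefficient_fit(ev: NodeEvaluator, expos, reference: StateTrajectory,
                            y0_scaled, n_fit: int = 60):
    """Per-state linear LSQ of coefficients to the reference trajectory,
    with the initial condition eliminated (fit in the c_1.. subspace)."""
    frame = ev.frame
    tgrid = np.linspace(frame.domain_length / n_fit, frame.domain_length, n_fit)
    ref = reference.sample(tgrid)
    coeffs = []
    for i, m in enumerate(ev.sizes):
        spec = BasisSpec(size=m, exponents=expos[i])
        powers = spec.powers
        P = tgrid[:, None] ** powers[None, :]
        D = ev.coeff_matrices[i].entries
        L = P @ D.T                                   # GLP values: L[:, a]
        A = L[:, 1:] - L[:, [0]]                      # eliminate c_0
        target = ref[:, i] - y0_scaled[i] * L[:, 0]
        rest, *_ = np.linalg.lstsq(A, target, rcond=None)
        coeffs.append(np.concatenate(([y0_scaled[i] - rest.sum()], rest)))
    return coeffs


def multistart_schedule(seed: int, k: int, bounds, problem: SpectralProblem,
                        reference: StateTrajectory | None = None,
                        reference_steps: int = 800):
    """Deterministic list of k starting points (coefficients, exponents).

    Start 1 is always the zero-exponent basis with coefficients from a
    linear least-squares fit to the coarse reference trajectory; the
    remaining starts draw exponents uniformly within bounds (coefficients
    refit linearly against the same reference).
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    lo, hi = bounds
    sizes = problem.sizes
    frame = problem.frame()
    y0_scaled = problem.init.as_array() / frame.state_scales
    if reference is None:
        reference = problem.reference_trajectory(steps=reference_steps)
    rule = QuadratureRule.gauss_legendre(problem.node_count, frame.domain_length)
    ev = NodeEvaluator(problem.params, problem.orders, sizes, frame, rule)
    rng = np.random.default_rng(seed)
    starts = []
    for j in range(k):
        if j == 0:
            expos = [np.zeros(m) for m in sizes]
        else:
            expos = [rng.uniform(lo[i], hi[i]) for i, m in enumerate(sizes)]
        expos = _clip_exponents(expos, bounds, sizes)
        coeffs = _linear_coefficient_fit(ev, expos, reference, y0_scaled)
        starts.append((coeffs, expos))
    return starts


# ---------------------------------------------------------------------------
# Stationarity system (Lagrangian gradient)
# ---------------------------------------------------------------------------

def stationarity_system(point: dict, problem: SpectralProblem):
    """Gradient blocks (dJ/dxi, dJ/dC, dJ/dExponents) at a point.

    ``point`` carries 'coefficients' (four full vectors), 'exponents'
    (four vectors) and 'multipliers' (length-4 xi).  The xi-block equals
    the constraint vector exactly.
    """
    coeffs = [np.asarray(c, dtype=float) for c in point["coefficients"]]
    expos = [np.asarray(b, dtype=float) for b in point["exponents"]]
    xi = np.asarray(point.get("multipliers", np.zeros(4)), dtype=float)
    ev = problem.evaluator()
    frame = problem.frame()
    y0_scaled = problem.init.as_array() / frame.state_scales

    theta = np.array([c.sum() - y0_scaled[i] for i, c in enumerate(coeffs)])

    pk = _Packing(problem.sizes, y0_scaled, optimize_exponents=True,
                  eliminate=False)
    model = _ResidualModel(ev, pk)
    x = pk.pack(coeffs, expos)
    grad = model.gradient(x)
    gC = grad[:pk.n_coeff].copy()
    gB = grad[pk.n_coeff:]
    # dTheta_i/dc_a^i = 1 for every a
    pos = 0
    for i, m in enumerate(problem.sizes):
        gC[pos:pos + m + 1] += xi[i]
        pos += m + 1
    return theta, gC, gB


# ---------------------------------------------------------------------------
# Solvers
# ---------------------------------------------------------------------------

def _literal_objective(ev: NodeEvaluator, coeffs, bases) -> float:
    r = ev.residual_nodes(coeffs, bases)
    factors = ev.literal_residual_factors()
    r_lit = r * factors[None, :]
    w_lit = ev.rule.weights * ev.frame.stretch
    return float(np.sum(w_lit[:, None] * r_lit * r_lit))


def solve(problem: SpectralProblem, cfg: SolverConfig = SolverConfig(),
          starts=None) -> SolveResult:
    """Best-of-multistart minimization of the residual objective."""
    if cfg.mode == "kkt":
        return _solve_kkt(problem, cfg)
    ev = problem.evaluator()
    frame = problem.frame()
    y0_scaled = problem.init.as_array() / frame.state_scales
    bounds = cfg.bounds_for(problem.sizes)
    if starts is None:
        starts = multistart_schedule(cfg.seed, cfg.multistarts, bounds, problem,
                                     reference_steps=cfg.reference_steps)
    pk = _Packing(problem.sizes, y0_scaled,
                  optimize_exponents=cfg.optimize_exponents, eliminate=True)
    lo, hi = bounds
    if cfg.optimize_exponents:
        xlo = np.concatenate([np.full(pk.n_coeff, -np.inf)] + [np.asarray(b) for b in lo])
        xhi = np.concatenate([np.full(pk.n_coeff, np.inf)] + [np.asarray(b) for b in hi])
    else:
        xlo, xhi = np.full(pk.size, -np.inf), np.full(pk.size, np.inf)

    best = None
    log = []
    for idx, (coeffs, expos) in enumerate(starts):
        expos = _clip_exponents(expos, bounds, problem.sizes)
        model = _ResidualModel(ev, pk, fixed_exponents=expos)
        x0 = pk.pack(coeffs, expos)
        x0 = np.clip(x0, xlo + 0.0, xhi - 0.0)
        res = least_squares(
            model.residuals, x0, jac=model.jacobian, bounds=(xlo, xhi),
            method="trf", xtol=1e-14, ftol=1e-14, gtol=cfg.gradient_tol,
            max_nfev=cfg.max_iterations,
        )
        log.append({"start": idx, "cost": 2.0 * res.cost,
                    "status": int(res.status), "nfev": int(res.nfev)})
        if best is None or res.cost < best[1].cost:
            best = (idx, res, model)
    idx, res, model = best
    coeffs, expos = pk.unpack(res.x, model.fixed_exponents)
    bases = [BasisSpec(size=m, exponents=b)
             for m, b in zip(problem.sizes, expos)]
    q_star = model.objective(res.x)
    theta = np.array([c.sum() - y0_scaled[i] for i, c in enumerate(coeffs)])
    converged = res.status > 0
    result = SolveResult(
        coefficients=coeffs,
        exponents=expos,
        multipliers=None,
        objective=q_star,
        literal_objective=_literal_objective(ev, coeffs, bases),
        constraint_residual=float(np.max(np.abs(theta))),
        success=bool(converged),
        message=("converged" if converged
                 else f"iteration budget exhausted (status {res.status})"),
        diagnostics={"starts": log, "best_start": idx,
                     "optimality": float(res.optimality),
                     "mode": cfg.mode, "seed": cfg.seed},
        problem=problem,
    )
    return result


def grow_solve(problem: SpectralProblem, cfg: SolverConfig,
               start_sizes=None) -> SolveResult:
    """Nested-basis continuation: grow every size by one, warm-started.

    Starting from ``start_sizes`` (default: all ones), each stage solves,
    then pads the best coefficients with a zero and re-seeds the next stage
    with that point alongside the regular multistart schedule.  Because the
    padded start represents the same function, the best objective is
    non-increasing across stages — the practical counterpart of the
    spectral convergence guarantees.
    """
    target = problem.sizes
    sizes = tuple(start_sizes) if start_sizes is not None \
        else tuple(min(2, m) for m in target)
    prev = None
    growth_log = []
    while True:
        stage = SpectralProblem(problem.params, problem.orders, problem.init,
                                problem.horizon, sizes,
                                node_count=problem.node_count,
                                normalized=problem.normalized,
                                forcing=problem.forcing)
        bounds = cfg.bounds_for(sizes)
        starts = multistart_schedule(cfg.seed, cfg.multistarts, bounds, stage,
                                     reference_steps=cfg.reference_steps)
        if prev is not None:
            padded_c = []
            padded_b = []
            for c, b, m_new in zip(prev.coefficients, prev.exponents, sizes):
                grow = m_new - (len(c) - 1)
                padded_c.append(np.concatenate([c, np.zeros(grow)]))
                padded_b.append(np.concatenate([b, np.zeros(grow)]))
            starts = [(padded_c, padded_b)] + starts
        result = solve(stage, cfg, starts=starts)
        if prev is not None and result.objective > prev.objective:
            result = prev          # keep the better iterate (padded anew next stage)
        growth_log.append({"sizes": sizes, "objective": result.objective})
        prev = result
        if sizes == target:
            result.diagnostics = dict(result.diagnostics, growth=growth_log)
            return result
        sizes = tuple(min(m + 1, t) for m, t in zip(sizes, target))


def _solve_kkt(problem: SpectralProblem, cfg: SolverConfig) -> SolveResult:
    """Damped Newton with backtracking line search on the KKT system."""
    frame = problem.frame()
    y0_scaled = problem.init.as_array() / frame.state_scales
    bounds = cfg.bounds_for(problem.sizes)
    warm_cfg = replace(cfg, mode="eliminate-ic")
    warm = solve(problem, warm_cfg)

    sizes = problem.sizes
    n_c = sum(m + 1 for m in sizes)
    n_b = sum(sizes) if cfg.optimize_exponents else 0

    def split(z):
        coeffs, pos = [], 0
        for m in sizes:
            coeffs.append(z[pos:pos + m + 1]); pos += m + 1
        expos = []
        if cfg.optimize_exponents:
            for m in sizes:
                expos.append(z[pos:pos + m]); pos += m
        else:
            expos = [np.asarray(b) for b in warm.exponents]
        xi = z[pos:pos + 4]
        return coeffs, expos, xi

    def G(z):
        coeffs, expos, xi = split(z)
        theta, gC, gB = stationarity_system(
            {"coefficients": coeffs, "exponents": expos, "multipliers": xi},
            problem)
        parts = [gC]
        if cfg.optimize_exponents:
            parts.append(gB)
        parts.append(theta)
        return np.concatenate(parts)

    z = np.concatenate(
        [np.concatenate(warm.coefficients)]
        + ([np.concatenate(warm.exponents)] if cfg.optimize_exponents else [])
        + [np.zeros(4)])
    gval = G(z)
    n_iter = 0
    for n_iter in range(cfg.max_iterations):
        norm = np.linalg.norm(gval)
        if norm < cfg.gradient_tol * (1.0 + abs(warm.objective)):
            break
        # numerical Jacobian of the stationarity map
        nz = z.size
        Jg = np.empty((gval.size, nz))
        for j in range(nz):
            h = 1e-7 * max(1.0, abs(z[j]))
            zp = z.copy(); zp[j] += h
            Jg[:, j] = (G(zp) - gval) / h
        try:
            step = np.linalg.solve(Jg, -gval)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(Jg, -gval, rcond=None)[0]
        lam, accepted = 1.0, False
        for _ in range(30):
            z_try = z + lam * step
            g_try = G(z_try)
            if np.linalg.norm(g_try) < (1.0 - 1e-4 * lam) * norm:
                z, gval, accepted = z_try, g_try, True
                break
            lam *= 0.5
        if not accepted:
            break

    coeffs, expos, xi = split(z)
    expos = _clip_exponents(expos, bounds, sizes)
    bases = [BasisSpec(size=m, exponents=b) for m, b in zip(sizes, expos)]
    ev = problem.evaluator()
    q_star = float(np.sum(ev.rule.weights[:, None]
                          * ev.residual_nodes(coeffs, bases) ** 2))
    theta = np.array([c.sum() - y0_scaled[i] for i, c in enumerate(coeffs)])
    gnorm = float(np.linalg.norm(gval))
    ok = gnorm < max(cfg.gradient_tol * (1.0 + abs(q_star)), 1e-8) \
        and float(np.max(np.abs(theta))) <= max(cfg.constraint_tol, 1e-10)
    return SolveResult(
        coefficients=[np.asarray(c) for c in coeffs],
        exponents=[np.asarray(b) for b in expos],
        multipliers=np.asarray(xi),
        objective=q_star,
        literal_objective=_literal_objective(ev, coeffs, bases),
        constraint_residual=float(np.max(np.abs(theta))),
        success=bool(ok),
        message="converged" if ok else
        f"KKT Newton stalled at |G| = {gnorm:.3e} after {n_iter + 1} iterations",
        diagnostics={"grad_norm": gnorm, "iterations": n_iter + 1,
                     "mode": "kkt", "seed": cfg.seed},
        problem=problem,
    )
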