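# Methods

## The model

`fraclag` ships a four-state fractional tumor-immune interaction model for
lung cancer as its flagship application. The states are densities (cells) of
tumor cells T, active macrophages A, macrophages M, and normal host cells W,
governed by Caputo fractional equations of per-equation order v_i in (0, 1]:

    D^v1 T = d2^v1 T (1 - T / l2^v1) - theta^v1 T A - alpha1^v1 W T
    D^v2 A = rho1^v2 M A - h2^v2 A
    D^v3 M = d1^v3 M (1 - M / l1^v3) - rho2^v3 M A - h1^v3 M
    D^v4 W = d3^v4 W (1 - W / l3^v4) - alpha2^v4 W T

Raising each rate constant to its equation's order keeps every term in
cells/day^v. The default parameter set is the published lung-cancer fit
(growth rates d1 = 0.9, d2 = 0.5045, d3 = 0.6169 per day; carrying
capacities l1 = 5.0785e7, l2 = 2.7785e5, l3 = 5.4621e6 cells; death rates
h1 = 4.3884e-14, h2 = 0.8809 per day; interaction coefficients
rho1 = 0.0937, rho2 = 0.0122, theta = 0.0140, alpha1 = 4.3930e-14,
alpha2 = 0.7609 per cell-day), with initial state (5, 0, 20, 200) cells and
a 150-day horizon.

Two typographic ambiguities in the source material were resolved once: the
macrophage carrying-capacity divisor is implemented as l1^v3 (the form the
residual equations themselves use), and the parameter printed as theta_2 in
the value table is the theta of the equations — the model has a single
tumor-destruction rate.

A consequence of the published initial state worth stating plainly: with
A(0) = 0 the A-equation is proportional to A, so the exact solution has
A identically zero for all time. The solver and the reference integrator
both preserve this invariant manifold (see below), and tests cover A0 > 0
separately.

## Generalized Laguerre ansatz

Each state is approximated by a truncated series in a generalized Laguerre
family: the classical Laguerre coefficient pattern

    entry(i, j) = (-1)^j / j! * i! / (j! (i-j)!)   (lower triangular)

applied to monomials t^{k + beta_k} with free "control" exponents beta_k
(beta_0 = 0). The series is stored in matrix form c^T D Phi(t). Free
exponents turn the span into a Muntz-type system: short expansions can carry
fractional powers matched to the Caputo orders. With all beta = 0 the
classical polynomials are recovered exactly (tested against the three-term
recurrence).

Coefficient-matrix entries are built in exact integer arithmetic up to order
20 (with an optional `fractions.Fraction` view) and through log-gamma
differences beyond; the default order cap of 20 exists because the factorial
ratios ill-condition double precision long before they overflow, and
published uses of this basis stay below order 8. Exponent positivity is
enforced with a margin: k + beta_k >= 1e-3, which keeps quadrature of
t^{k+beta_k-v} well-behaved near t = 0. Series evaluation at t = 0 takes the
continuity limit (positive powers vanish).

## Caputo derivatives and the operational diagonal

The Caputo derivative acts on each monomial by the power rule
D^v t^p = Gamma(p+1)/Gamma(p-v+1) t^{p-v} (constants are annihilated), so
the derivative of a series is a diagonal action on the monomial vector:
gamma_k = Gamma(k+1+beta_k)/Gamma(k+1-v+beta_k) with a scalar t^{-v} rule.
The diagonal is stored as its factor vector, never as a dense per-time
matrix. All gamma ratios are computed as exp(logGamma(a) - logGamma(b)),
which stays finite for the large arguments the bounds diagnostics can
produce.

An independent L1 discretization of the convolution integral (piecewise-
linear interpolant, exact kernel integration per cell, uniform grid) serves
as the validation oracle for the operational path; it shares no code with
it. On a uniform grid it converges at order 2 - v for smooth integrands,
degrading toward first order when the integrand's derivative is singular at
the origin; the agreement tests therefore seed exponents in [0, 1], where
the oracle itself is reliable at 1e5 steps.

## Residuals, objective, constraints

Substituting the ansatz into the model leaves residuals R_i(t); the
objective is the Gauss–Legendre quadrature (default 64 nodes) of the summed
squared residuals over the horizon. Gauss nodes avoid t = 0, where the
operational form carries t^{-v}, and positive weights preserve Q >= 0.
The initial conditions are linear constraints: the monomial vector collapses
to [1, 0, ..., 0] at t = 0, so each series' initial value is simply its
coefficient sum. The Lagrangian J = Q + xi . Theta carries one multiplier
per constraint (four), since a single scalar cannot enforce four conditions.

Two frames are provided. The literal frame evaluates everything in days and
cells. The normalized frame — the optimizer default — maps time to
tau = t/zeta on (0, 1] with the Caputo chain-rule factor zeta^{-v_i},
scales states by (l2, max(1, A0), l1, l3), and divides residual i by
(scale_i * zeta^{-v_i}). Raw powers t^{m+beta} on [0, 150] combined with
states up to 1e7 make the literal problem numerically hopeless as an
optimization target; the literal frame is retained for reporting and for
direct comparison with the textbook objective. The two frames agree
identically up to the stated factors (tested to 1e-9 relative). Note that
the objective magnitudes of the two frames are not comparable: reported
optima of order 1e-9 for an unnormalized 150-day problem with states of
order 1e5 are not a reachable scale for this formulation, and no
normalization that would make them reachable is documented anywhere we
could follow; both frame values are therefore reported side by side and
neither is tuned toward any published figure.

## Optimization strategy

Q is a positive quadrature sum of squares, so the inner solver is
bound-constrained trust-region least squares (scipy `least_squares`, TRF) on
the stacked weighted node residuals, with analytic Jacobians for both
coefficients and exponents (the exponent columns use digamma differences for
the derivative of the gamma ratios). Two constraint treatments:

* **eliminate-ic** (default): because each constraint is "coefficient sum
  equals initial value", one coefficient per state is eliminated and the
  constraints hold to machine precision by construction.
* **kkt**: damped Newton with backtracking line search on the full
  stationarity system (constraints, coefficient gradient, exponent
  gradient, multipliers), mirroring the multiplier formulation literally.
  It is warm-started from an eliminate-ic solve.

Initialization is a deterministic seeded multistart (default 8 starts,
seed 0): start 1 is always the zero-exponent basis with coefficients from a
linear least-squares fit to a coarse (800-step) predictor-corrector
reference trajectory; the remaining starts draw exponents uniformly within
bounds and refit coefficients linearly. Identical configuration and seed
give bit-identical results, and start schedules are nested, so the
best-found objective is non-increasing in the number of starts.

Exponent bounds default to beta_k in [-min(k - 1e-3, 0.9), 2]; the window
is configurable. Tolerances: gradient 1e-10 (normalized frame), constraint
1e-12, 500 iterations per start. Nested-basis continuation (`grow_solve`)
grows every basis size by one per stage, re-seeding with the zero-padded
previous optimum, which makes the best objective non-increasing across
stages.

## Reference predictor-corrector

The validation oracle is a fractional Adams–Bashforth–Moulton scheme on a
uniform grid with full-memory sums (no short-memory truncation; correctness
over speed) and per-equation orders. Components with v = 1 use O(N) running
memory sums (the Adams weights collapse to constants); fractional components
use the standard O(N^2) weighted sums.

The corrector stage is solved implicitly by **component-wise damped Newton**
rather than the classical single functional sweep, for two reasons observed
directly on the flagship model. First, stiffness: once the tumor population
saturates, host cells decay at rate alpha2 * T ≈ 2e5/day, and any explicit
corrector overflows at practical step counts. Second, invariant manifolds:
the A = 0 manifold is dynamically unstable (growth rate up to rho1 * l1 ≈
4.7e6/day), so a corrector that couples components through a full Newton
solve reseeds A with roundoff that then amplifies catastrophically; the
component-wise update never writes into a component whose corrector residual
is exactly zero, preserving A = 0 to the bit. The classical explicit sweep
variant remains available (`corrector="sweeps"`) and is the right choice for
non-stiff problems. The scheme remains the standard predictor-corrector pair
with fractional Adams weights; only the corrector-equation solve is
stabilized, and no claim of stiff-solver generality is made.

Step counts: 4096 steps for qualitative 150-day runs; the integer-order
cross-validation against a classical stiff integrator uses 131072 steps,
where the observed normalized deviation is a few times 1e-7. A truncated
high-precision series (with an algebraic asymptotic branch for large
negative arguments) provides Mittag-Leffler values for closed-form checks
on linear scalar problems.

## Manufactured problems

Verification fixtures prescribe an exact solution inside a chosen GLP span,
derive the forcing g_i = D^v x_i* - f_i(x*) that makes it solve the forced
model, and ask the solver to recover it. Generation is seeded and
deterministic: exponents uniform in [0, 2] (inside the solver window, and
keeping the manufactured Caputo derivative bounded at the origin),
amplitude magnitudes uniform in [0.5, 2] with random signs, leading
coefficients adjusted so initial values are nonnegative. Problems live on a
unit horizon with unscaled O(1) states — well-conditioned by construction.
Recovery runs solve with the exponents held at their known values, which
tests the coefficient path end to end; exponent estimation is exercised
separately by the model runs.

## Error-bound diagnostics

Three desk-scale bounds are computed numerically: the truncation tail bound
M * sum |c_k| over dropped coefficients; the Taylor-type best-approximation
bound L M A^{m+1}/(m+1)!; and its Caputo image with the 1/Gamma(n - v)
factor and indices shifted by the integer ceiling n of the order. The sups
M and L are grid maxima over [0, 1] (1e4 points by default) and are
documented lower bounds of the true sups — sufficient for diagnostics. The
derivative-error bound is stated with the printed (m - k + 1) indices of its
source even though the tightest consistent index would differ by one; the
empirical domination suite uses functions (decaying-coefficient series,
exp(t/2)) for which the printed form provably dominates.

## What the tests do and do not show

The synthetic manufactured problems emulate the model's algebraic structure
(logistic growth, bilinear interactions, mixed Caputo orders) with O(1)
states on a unit horizon. They do not emulate the published scenario's two
hard features: state magnitudes spanning nine decades and logistic fronts
that are sharp relative to the horizon. Passing the recovery suite
therefore demonstrates correctness of the assembly/derivative/optimizer
chain, not approximation power on sharp-front problems.

On approximation power, a package-level finding: at integer order the
published parameter set drives T and M through logistic fronts whose widths
are a few days against a 150-day horizon. The best possible 13-term
free-exponent approximant (global search over exponents, least-squares
coefficients) still has normalized sup error of roughly 0.11 for T and 0.16
for M; any residual-minimized solution lies in the same span and can do no
better in sup norm. Basis sizes near 40 would be needed for a few-percent
sup-norm match of these fronts. The cross-validation suite states this
plainly: the integer-order comparison between the two *time-stepping* routes
(predictor-corrector vs classical stiff integrator) agrees to 1e-6, while
the spectral trajectories at basis sizes up to 12 track the reference only
to the 0.1-0.3 level on the front states.

## Reproducibility limits of published tables

Two kinds of published figures are explicitly out of reach and are not
acceptance surfaces for this package. Wall-clock runtime tables are
hardware- and implementation-dependent and are not reproducible on other
machines; this package reports its own wall times in run reports and makes
no cross-machine claims. Published residual-norm optima obtained from a
proprietary CAS root-finder applied to this nonconvex problem — with no
stated initialization, scaling, or tolerance — are solver-trajectory
artifacts; they are likewise not reproducible and are replaced here by
property-based checks (oracle agreement, manufactured-solution recovery,
qualitative scenario reproduction, bound domination).

## Numerical choices summary

| Quantity | Default | Why |
| --- | --- | --- |
| Quadrature nodes | 64 Gauss–Legendre on (0, zeta] | avoids t = 0 singularity; positive weights |
| Basis size cap | 20 (override flag) | factorial conditioning; published use <= 7 |
| Exponent window | [-min(k - 1e-3, 0.9), 2] | positivity margin + sane search box |
| Multistarts / seed | 8 / 0 | reproducible exploration |
| Gradient / constraint tol | 1e-10 / 1e-12 | normalized-frame scales |
| Reference steps | 4096 (150 d) | full-memory cost vs accuracy |
| Integer-order validation steps | 131072 | observed ~3e-7 normalized deviation |
| Report grid | 301 points | figure-density sampling, decoupled from quadrature |
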