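"""Caputo fractional calculus on power functions and GLP series.

The Caputo derivative of order v in (0, 1] acts on a power t^p (p > 0) as

    D^v t^p = Gamma(p+1) / Gamma(p-v+1) * t^{p-v},        D^v const = 0,

the ordinary derivative being the v = 1 limit.  Because a GLP series is a
finite combination of such powers, its Caputo derivative is obtained by a
diagonal "operational" action on the monomial vector: entry i of Phi is
multiplied by gamma_i * t^{-v} with gamma_i = Gamma(i+1+beta_i) /
Gamma(i+1-v+beta_i) and gamma_0 = 0.

A uniform-grid L1 discretization of the convolution integral is provided as
an independent oracle (`gl_caputo_oracle`); it shares no code with the
operational path.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import gammaln

from .basis import ApproximantSeries, BasisSpec

__all__ = [
    "FractionalOrder",
    "CaputoPowerResult",
    "OperationalDiagonal",
    "gamma_ratio",
    "caputo_power",
    "operational_diagonal",
    "caputo_derivative_series",
    "caputo_series_limit_at_zero",
    "gl_caputo_oracle",
]


@dataclass(frozen=True)
class FractionalOrder:
    """A Caputo order v with 0 < v <= 1."""

    value: float

    def __post_init__(self) -> None:
        v = float(self.value)
        if not 0.0 < v <= 1.0:
            raise ValueError(f"fractional order must lie in (0, 1], got {v}")
        object.__setattr__(self, "value", v)


def _as_order(v) -> float:
    return v.value if isinstance(v, FractionalOrder) else FractionalOrder(v).value


def gamma_ratio(a: float, b: float) -> float:
    """Gamma(a)/Gamma(b) through log-gamma differences (overflow-safe)."""
    return float(np.exp(gammaln(a) - gammaln(b)))


@dataclass(frozen=True)
class CaputoPowerResult:
    """D^v t^p written as coefficient * t^exponent (or identically zero)."""

    coefficient: float
    exponent: float
    is_zero: bool

    def __call__(self, t: float) -> float:
        if self.is_zero:
            return 0.0
        t = float(t)
        if t == 0.0:
            # limit value: 0 when the exponent is positive, the coefficient
            # itself when the exponent vanishes (p == v).
            if self.exponent > 0:
                return 0.0
            if self.exponent == 0:
                return self.coefficient
            return np.inf * np.sign(self.coefficient)
        return self.coefficient * t ** self.exponent


def caputo_power(p: float, v) -> CaputoPowerResult:
    """Caputo derivative of t^p for real p >= 0 and order v in (0, 1]."""
    p = float(p)
    v = _as_order(v)
    if p < 0:
        raise ValueError(f"caputo_power requires p >= 0, got {p}")
    if p == 0.0:
        return CaputoPowerResult(coefficient=0.0, exponent=0.0, is_zero=True)
    return CaputoPowerResult(
        coefficient=gamma_ratio(p + 1.0, p - v + 1.0),
        exponent=p - v,
        is_zero=False,
    )


@dataclass(frozen=True)
class OperationalDiagonal:
    """Diagonal operational matrix of the Caputo derivative on a GLP basis.

    Stored as the factor vector gamma plus the scalar t^{-v} rule: the
    action on Phi(t) multiplies entry i by gamma_i * t^{-v}.  gamma_0 = 0
    (constants are annihilated).
    """

    factors: np.ndarray
    order: float
    basis: BasisSpec

    def apply(self, phi: np.ndarray, t: float) -> np.ndarray:
        t = float(t)
        if t <= 0:
            raise ValueError("operational action requires t > 0")
        return self.factors * phi * t ** (-self.order)

    def derivative_monomials(self, t: float) -> np.ndarray:
        """[0, gamma_1 t^{1+b_1-v}, ...]: the Caputo derivative of Phi at t."""
        t = float(t)
        if t <= 0:
            raise ValueError("operational action requires t > 0")
        powers = self.basis.powers - self.order
        out = np.zeros_like(self.factors)
        out[1:] = self.factors[1:] * t ** powers[1:]
        return out


def operational_diagonal(spec: BasisSpec, v) -> OperationalDiagonal:
    """gamma_i = Gamma(i+1+beta_i)/Gamma(i+1-v+beta_i), gamma_0 = 0."""
    v = _as_order(v)
    m = spec.size
    factors = np.zeros(m + 1)
    for i in range(1, m + 1):
        b = spec.exponents[i - 1]
        factors[i] = gamma_ratio(i + 1.0 + b, i + 1.0 - v + b)
    return OperationalDiagonal(factors=factors, order=v, basis=spec)


def caputo_derivative_series(s: ApproximantSeries, v, t: float) -> float:
    """Caputo derivative of a GLP series at t > 0 via the diagonal action."""
    t = float(t)
    if t <= 0:
        raise ValueError(
            "caputo_derivative_series requires t > 0; "
            "use caputo_series_limit_at_zero for the t -> 0 limit"
        )
    diag = operational_diagonal(s.basis, v)
    return float(s.monomial_weights @ diag.derivative_monomials(t))


def caputo_series_limit_at_zero(s: ApproximantSeries, v) -> float:
    """Per-term limit of D^v series as t -> 0+.

    Terms with exponent p > v tend to 0; a term with p == v contributes its
    constant Gamma(p+1)/Gamma(p-v+1); any term with 0 < p < v diverges, in
    which case inf with the sign of the driving weight is returned.
    """
    v = _as_order(v)
    g = s.monomial_weights
    powers = s.basis.powers
    total = 0.0
    for i in range(1, s.basis.size + 1):
        if g[i] == 0.0:
            continue
        p = powers[i]
        if p > v:
            continue
        coeff = g[i] * gamma_ratio(p + 1.0, p - v + 1.0)
        if p == v:
            total += coeff
        else:
            return float(np.inf * np.sign(coeff))
    return total


def gl_caputo_oracle(f, v, t: float, steps: int = 4096) -> float:
    """L1 discretization of the Caputo convolution integral (test oracle).

    The integrand's ordinary derivative is replaced by the piecewise-linear
    slope on a uniform grid, and the kernel (t-s)^{-v} is integrated exactly
    on each cell.  First-order convergent in 1/steps for smooth f.  v = 1 is
    handled as the ordinary backward difference at t.
    """
    t = float(t)
    v = _as_order(v)
    if t <= 0:
        raise ValueError("gl_caputo_oracle requires t > 0")
    if steps < 16:
        raise ValueError("at least 16 steps are required")
    h = t / steps
    if v == 1.0:
        return (f(t) - f(t - h)) / h
    grid = np.linspace(0.0, t, steps + 1)
    try:                      # vectorized evaluation when f supports it
        fvals = np.asarray(f(grid), dtype=float)
        if fvals.shape != grid.shape:
            raise TypeError
    except Exception:
        fvals = np.asarray([f(x) for x in grid], dtype=float)
    slopes = np.diff(fvals) / h
    # integral of (t - s)^{-v} over cell [s_k, s_{k+1}]:
    #   ((t-s_k)^{1-v} - (t-s_{k+1})^{1-v}) / (1-v)
    tail = (t - grid) ** (1.0 - v)
    weights = (tail[:-1] - tail[1:]) / (1.0 - v)
    from scipy.special import gamma as _gamma

    return float(np.dot(slopes, weights) / _gamma(1.0 - v))
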