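"""Generalized Laguerre polynomial (GLP) bases with free exponents.

The classical Laguerre polynomials on the line,

    L_m(t) = sum_{k=0}^m (-1)^k / k! * m! / (k! (m-k)!) * t^k,

are generalized here by replacing the monomial t^k with t^{k + beta_k},
where the "control parameters" beta_k are free real exponents (beta_0 = 0,
so the constant term is untouched).  Setting every beta_k = 0 recovers the
classical polynomials.  A truncated series in this family is stored in the
matrix form  c^T D Phi(t):  coefficients c, the lower-triangular Laguerre
coefficient matrix D, and the monomial vector Phi(t) = [1, t^{1+beta_1},
..., t^{m+beta_m}].  The free exponents turn the span into a Muntz-type
system, which is what lets short expansions track fractional-power and
boundary-layer behaviour.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction

import numpy as np
from scipy.special import gammaln

__all__ = [
    "BasisSpec",
    "CoefficientMatrix",
    "ApproximantSeries",
    "build_coefficient_matrix",
    "monomial_vector",
    "evaluate_glp",
    "evaluate_series",
    "DEFAULT_SIZE_CAP",
    "EXPONENT_MARGIN",
]

#: Largest basis size accepted without an explicit override.  The closed-form
#: coefficients involve factorial ratios that ill-condition double precision
#: well before they overflow; published uses never exceed m = 7.
DEFAULT_SIZE_CAP = 20

#: Positivity margin for the effective exponents i + beta_i.  Strict
#: positivity is the defining requirement; the margin keeps quadrature of
#: t^{i+beta_i-v} well-behaved near t = 0.
EXPONENT_MARGIN = 1e-3


@dataclass(frozen=True)
class BasisSpec:
    """A GLP family: highest index ``size`` and exponents beta_1..beta_m.

    beta_0 is implicitly 0 (the constant term carries no free exponent).
    """

    size: int
    exponents: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        if self.size < 0:
            raise ValueError(f"basis size must be nonnegative, got {self.size}")
        exps = np.atleast_1d(np.asarray(self.exponents, dtype=float))
        if self.size == 0:
            exps = np.zeros(0)
        if exps.shape != (self.size,):
            raise ValueError(
                f"expected {self.size} exponents, got shape {exps.shape}"
            )
        powers = np.arange(1, self.size + 1) + exps
        if np.any(powers < EXPONENT_MARGIN):
            bad = int(np.argmin(powers)) + 1
            raise ValueError(
                f"effective exponent {bad}+beta_{bad} = {powers[bad - 1]:g} "
                f"violates the positivity margin {EXPONENT_MARGIN:g}"
            )
        object.__setattr__(self, "exponents", exps)

    @classmethod
    def classical(cls, size: int, label: str = "") -> "BasisSpec":
        """All beta = 0: the classical Laguerre polynomials."""
        return cls(size=size, exponents=np.zeros(size), label=label)

    @property
    def powers(self) -> np.ndarray:
        """Effective monomial powers [0, 1+beta_1, ..., m+beta_m]."""
        return np.concatenate(([0.0], np.arange(1, self.size + 1) + self.exponents))


@dataclass(frozen=True)
class CoefficientMatrix:
    """Lower-triangular matrix of Laguerre expansion coefficients.

    entry(i, j) = (-1)^j / j! * i! / (j! (i-j)!) for i >= j, else 0.  Row i
    holds the monomial coefficients of the i-th (generalized) Laguerre
    polynomial; the same matrix serves every exponent choice because the
    generalization only swaps the monomials, not the coefficients.
    """

    order: int
    entries: np.ndarray
    exact: tuple = field(default=None, repr=False, compare=False)

    def row(self, i: int) -> np.ndarray:
        return self.entries[i]


def _coefficient_entry_log(i: int, j: int) -> float:
    # log |entry| = log(i!) - 2 log(j!) - log((i-j)!)
    return gammaln(i + 1) - 2.0 * gammaln(j + 1) - gammaln(i - j + 1)


def build_coefficient_matrix(m: int, *, rational: bool = False,
                             allow_large: bool = False) -> CoefficientMatrix:
    """Build the (m+1) x (m+1) lower-triangular Laguerre coefficient matrix.

    Parameters
    ----------
    m
        Highest basis index (matrix order).
    rational
        Also carry exact ``fractions.Fraction`` entries (m <= 20 only);
        available as ``CoefficientMatrix.exact``.
    allow_large
        Permit m beyond the default cap of 20.  Entries are then evaluated
        through log-gamma differences, which stay finite long after direct
        factorials overflow.
    """
    if m < 0:
        raise ValueError(f"matrix order must be nonnegative, got {m}")
    if m > DEFAULT_SIZE_CAP and not allow_large:
        raise ValueError(
            f"order {m} exceeds the cap {DEFAULT_SIZE_CAP}; "
            "pass allow_large=True to override"
        )
    entries = np.zeros((m + 1, m + 1))
    if m <= DEFAULT_SIZE_CAP:
        # Exact integer arithmetic, then a single rounding to double.
        fac = [1] * (m + 1)
        for i in range(1, m + 1):
            fac[i] = fac[i - 1] * i
        exact_rows = []
        for i in range(m + 1):
            row = []
            for j in range(m + 1):
                if j > i:
                    row.append(Fraction(0))
                else:
                    val = Fraction((-1) ** j * fac[i], fac[j] * fac[j] * fac[i - j])
                    row.append(val)
                    entries[i, j] = float(val)
            exact_rows.append(tuple(row))
        exact = tuple(exact_rows) if rational else None
    else:
        if rational:
            raise ValueError("rational mode is limited to m <= 20")
        for i in range(m + 1):
            for j in range(i + 1):
                entries[i, j] = (-1) ** j * np.exp(_coefficient_entry_log(i, j))
        exact = None
    return CoefficientMatrix(order=m, entries=entries, exact=exact)


def monomial_vector(t: float, spec: BasisSpec) -> np.ndarray:
    """Evaluate Phi(t) = [1, t^{1+beta_1}, ..., t^{m+beta_m}].

    Non-integer powers are undefined for t < 0; at t = 0 every positive
    power is taken as its limit 0, so Phi(0) = [1, 0, ..., 0].
    """
    t = float(t)
    if t < 0:
        raise ValueError(f"monomial vector requires t >= 0, got {t}")
    powers = spec.powers
    out = np.zeros(powers.shape)
    out[0] = 1.0
    if t > 0:
        out[1:] = t ** powers[1:]
    return out


def evaluate_glp(m: int, beta, t: float) -> float:
    """Evaluate the m-th generalized Laguerre polynomial at t >= 0.

    ``beta`` may be a scalar (broadcast to all indices) or a length-m vector.
    """
    beta = np.asarray(beta, dtype=float)
    if beta.ndim == 0:
        beta = np.full(m, float(beta))
    spec = BasisSpec(size=m, exponents=beta)
    D = build_coefficient_matrix(m)
    return float(D.row(m) @ monomial_vector(t, spec))


@dataclass(frozen=True)
class ApproximantSeries:
    """One state's ansatz  c^T D Phi(t)  over a GLP basis."""

    coefficients: np.ndarray
    basis: BasisSpec
    coefficient_matrix: CoefficientMatrix

    def __post_init__(self) -> None:
        c = np.atleast_1d(np.asarray(self.coefficients, dtype=float))
        n = self.basis.size + 1
        if c.shape != (n,):
            raise ValueError(
                f"coefficient vector has shape {c.shape}, expected ({n},)"
            )
        if self.coefficient_matrix.order != self.basis.size:
            raise ValueError(
                "coefficient matrix order "
                f"{self.coefficient_matrix.order} != basis size {self.basis.size}"
            )
        object.__setattr__(self, "coefficients", c)

    @classmethod
    def from_coefficients(cls, coefficients, basis: BasisSpec) -> "ApproximantSeries":
        return cls(
            coefficients=np.asarray(coefficients, dtype=float),
            basis=basis,
            coefficient_matrix=build_coefficient_matrix(basis.size),
        )

    @property
    def monomial_weights(self) -> np.ndarray:
        """g = D^T c, the weights attached to the raw monomials of Phi."""
        return self.coefficient_matrix.entries.T @ self.coefficients

    def __call__(self, t: float) -> float:
        return evaluate_series(self, t)


def evaluate_series(s: ApproximantSeries, t: float) -> float:
    """Evaluate  c^T D Phi(t)."""
    return float(s.monomial_weights @ monomial_vector(t, s.basis))
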