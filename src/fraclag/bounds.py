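"""Truncation and best-approximation error bounds as numerical diagnostics.

Three desk-scale bounds accompany the spectral machinery, each evaluated on
[0, 1]:

* a truncation tail bound — the error of dropping coefficients beyond index
  m is at most M * sum of the dropped |c_k|, with M the sup of |L_m| on the
  unit interval;
* a Taylor-type best-square-approximation bound L*M*A^{m+1}/(m+1)!, with L
  the sup of the (m+1)-th derivative and A = max(1-t0, t0) for the chosen
  expansion point t0;
* the same bound pushed through the Caputo operator, which contributes a
  1/Gamma(n-v) factor and shifts the factorial indices by the integer
  ceiling n of the order.

The sups M and L are computed as grid maxima (documented lower bounds of
the true sups), which is all a diagnostic needs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import gamma as _gamma, gammaln

from .basis import evaluate_glp

__all__ = [
    "BoundInputs",
    "truncation_tail_bound",
    "best_approx_bound",
    "caputo_error_bound",
    "glp_sup",
    "grid_sup",
]


@dataclass(frozen=True)
class BoundInputs:
    """Ingredients of the error bounds (all sups over [0, 1])."""

    M: float          # sup |L_m|
    L: float          # sup of the relevant derivative magnitude
    A: float          # max(1 - t0, t0)
    m: int
    k: int = 0
    n: int = 1
    order: float = 1.0

    def __post_init__(self) -> None:
        if min(self.M, self.L, self.A) < 0:
            raise ValueError("M, L, A must be nonnegative")


def glp_sup(m: int, beta=0.0, points: int = 10_000) -> float:
    """Grid maximum of |L_m| on [0, 1] (a lower bound of the true sup)."""
    grid = np.linspace(0.0, 1.0, points)
    vals = np.array([evaluate_glp(m, beta, t) for t in grid])
    return float(np.max(np.abs(vals)))


def grid_sup(f, points: int = 10_000) -> float:
    """Grid maximum of |f| on [0, 1]."""
    grid = np.linspace(0.0, 1.0, points)
    return float(np.max(np.abs([f(t) for t in grid])))


def truncation_tail_bound(tail_coeffs, M: float) -> float:
    """M * sum |c_k| over the supplied (finite) tail of dropped coefficients."""
    if M < 0:
        raise ValueError("M must be nonnegative")
    tail = np.asarray(tail_coeffs, dtype=float)
    if tail.size == 0:
        return 0.0
    return float(M * np.sum(np.abs(tail)))


def best_approx_bound(L: float, M: float, A: float, m: int) -> float:
    """L * M * A^(m+1) / (m+1)!  — Taylor-remainder bound on the L2 error."""
    if min(L, M, A) < 0:
        raise ValueError("L, M, A must be nonnegative")
    if m < 0:
        raise ValueError("m must be nonnegative")
    return float(L * M * A ** (m + 1) * np.exp(-gammaln(m + 2)))


def caputo_error_bound(L: float, M: float, A: float, m: int, n: int,
                       v: float) -> float:
    """(1/Gamma(n-v)) * L * M * A^(m-n+1) / (m-n+1)!.

    Requires m >= n >= 1 and n - v > 0 (for orders in (0, 1], n = 1 and
    v < 1).
    """
    if min(L, M, A) < 0:
        raise ValueError("L, M, A must be nonnegative")
    if not (m >= n >= 1):
        raise ValueError("require m >= n >= 1")
    if n - v <= 0:
        raise ValueError("require n - v > 0")
    j = m - n + 1
    return float(L * M * A ** j * np.exp(-gammaln(j + 1)) / _gamma(n - v))
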