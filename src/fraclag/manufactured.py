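"""Method-of-manufactured-solutions fixtures for the spectral solver.

A manufactured problem prescribes an exact solution that lies exactly in a
chosen GLP span, derives the forcing g_i(t) = D^{v_i} x_i* - f_i(x*) that
makes it solve the (forced) model, and asks the solver to recover it.  The
modified residuals R_i - g_i vanish identically at the exact solution, so
any surplus objective is solver error — the cleanest end-to-end check the
pipeline has.

Problems are generated on a unit horizon with unscaled O(1) states, which
keeps them well-conditioned without any frame gymnastics; the exponents are
drawn nonnegative so the manufactured Caputo derivative stays bounded at
the origin (the solver itself accepts the full exponent window).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .basis import ApproximantSeries, BasisSpec
from .caputo import caputo_derivative_series
from .model import (FractionalOrders, InitialState, ModelParameters,
                    default_parameters, rhs)
from .optimize import SpectralProblem

__all__ = ["ManufacturedProblem", "make_manufactured_problem"]


@dataclass(frozen=True)
class ManufacturedProblem:
    """A forced model problem with a known in-span exact solution."""

    target_coefficients: tuple     # four coefficient vectors (amplitudes)
    exponents: tuple               # four exponent vectors
    orders: FractionalOrders
    params: ModelParameters
    init: InitialState
    horizon: float
    seed: int

    @property
    def sizes(self) -> tuple:
        return tuple(len(b) for b in self.exponents)

    def exact_series(self) -> list:
        return [
            ApproximantSeries.from_coefficients(
                c, BasisSpec(size=len(b), exponents=np.asarray(b)))
            for c, b in zip(self.target_coefficients, self.exponents)
        ]

    def exact_state(self, t) -> np.ndarray:
        series = self.exact_series()
        t = np.atleast_1d(np.asarray(t, dtype=float))
        return np.stack([[s(x) for s in series] for x in t])

    def forcing(self, t: float) -> np.ndarray:
        """g(t) = D^v x*(t) - f(x*(t)), the induced forcing at t > 0."""
        series = self.exact_series()
        orders = self.orders.as_array()
        deriv = np.array([
            caputo_derivative_series(s, orders[i], t)
            for i, s in enumerate(series)
        ])
        x = np.array([s(t) for s in series])
        return deriv - rhs(x, self.params, self.orders)

    def spectral_problem(self, node_count: int = 48) -> SpectralProblem:
        """The forced problem in the solver's own container (literal frame)."""
        return SpectralProblem(
            params=self.params, orders=self.orders, init=self.init,
            horizon=self.horizon, sizes=self.sizes, node_count=node_count,
            normalized=False, forcing=self.forcing,
        )


def make_manufactured_problem(seed: int, v: FractionalOrders, sizes,
                              params: ModelParameters | None = None,
                              horizon: float = 1.0) -> ManufacturedProblem:
    """Deterministic fixture: exact solution in the GLP span of ``sizes``.

    Exponents are drawn uniformly in [0, 2] (inside the solver's default
    window and with bounded Caputo derivatives); amplitude magnitudes are
    uniform in [0.5, 2] with random signs, the leading coefficient adjusted
    so every initial value is nonnegative.
    """
    sizes = tuple(int(m) for m in sizes)
    if any(m < 1 for m in sizes):
        raise ValueError("every size must be >= 1")
    if params is None:
        params = default_parameters()
    rng = np.random.default_rng(seed)
    coeff_sets, expo_sets = [], []
    for m in sizes:
        beta = rng.uniform(0.0, 2.0, size=m)
        mags = rng.uniform(0.5, 2.0, size=m)
        signs = rng.choice([-1.0, 1.0], size=m)
        rest = mags * signs
        c0 = rng.uniform(0.5, 2.0)
        if c0 + rest.sum() < 0:
            c0 = -rest.sum() + rng.uniform(0.5, 2.0)
        coeff_sets.append(np.concatenate(([c0], rest)))
        expo_sets.append(beta)
    init = InitialState(*(float(c.sum()) for c in coeff_sets))
    return ManufacturedProblem(
        target_coefficients=tuple(coeff_sets),
        exponents=tuple(expo_sets),
        orders=v, params=params, init=init,
        horizon=float(horizon), seed=int(seed),
    )
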