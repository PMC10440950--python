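"""Fractional Adams-Bashforth-Moulton predictor-corrector (validation oracle).

Time-stepping for Caputo systems D^{v_i} y_i = f_i(t, y) on a uniform grid,
with the standard fractional Adams weights and full-memory sums (no
short-memory truncation).  Each component carries its own order v_i, so
mixed-order systems integrate consistently.  At v = 1 the scheme reduces to
the classical Euler-predictor / trapezoid-corrector pair.

This solver is deliberately independent of the spectral machinery: it is
used to cross-validate GLP solutions and to seed the optimizer, never the
other way around.  A truncated-series Mittag-Leffler evaluator is included
for closed-form solutions of linear scalar test problems.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import gamma as _gamma

__all__ = ["StateTrajectory", "SolverFailure", "abm_solve", "mittag_leffler"]


@dataclass(frozen=True)
class StateTrajectory:
    """Uniform-grid trajectory: times (N+1,), states (N+1, d)."""

    times: np.ndarray
    states: np.ndarray
    orders: np.ndarray
    step_count: int

    def __post_init__(self) -> None:
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("time grid must be strictly increasing")

    def sample(self, t) -> np.ndarray:
        """Linear interpolation onto arbitrary times within the grid."""
        t = np.atleast_1d(np.asarray(t, dtype=float))
        cols = [np.interp(t, self.times, self.states[:, i])
                for i in range(self.states.shape[1])]
        return np.stack(cols, axis=1)


class SolverFailure(RuntimeError):
    """Raised when the state leaves the finite range mid-integration."""

    def __init__(self, message: str, last_valid_index: int,
                 partial: StateTrajectory | None = None):
        super().__init__(message)
        self.last_valid_index = last_valid_index
        self.partial = partial


def _orders_array(v, dim: int) -> np.ndarray:
    from .model import FractionalOrders

    if isinstance(v, FractionalOrders):
        arr = v.as_array()
    else:
        arr = np.atleast_1d(np.asarray(v, dtype=float))
        if arr.size == 1:
            arr = np.full(dim, arr[0])
    if arr.shape != (dim,):
        raise ValueError(f"expected {dim} orders, got shape {arr.shape}")
    if np.any(arr <= 0) or np.any(arr > 1):
        raise ValueError("orders must lie in (0, 1]")
    return arr


def _newton_corrector(rhs, t, y0_base, pre, y_guess, tol=1e-12, max_iter=25):
    """Solve y = y0_base + pre * f(t, y) by component-wise damped Newton.

    Each component is updated with its own diagonal derivative (Jacobi
    sweeps re-evaluating f between updates).  This keeps the corrector
    stable when an equation is stiff in its own state — for the tumor
    model, host-cell depletion at rate alpha2*T once the tumor saturates —
    while never writing into components whose residual is exactly zero, so
    invariant manifolds like A = 0 are preserved to the bit.
    """
    d = y_guess.size
    y = y_guess.copy()
    if not np.all(np.isfinite(y)):
        y = y0_base.copy()
    scale = np.maximum(1.0, np.abs(y0_base))
    for _ in range(max_iter):
        try:
            f = np.asarray(rhs(t, y), dtype=float)
        except FloatingPointError:
            f = np.full(d, np.nan)
        if not np.all(np.isfinite(f)):
            # retreat halfway toward the memory baseline
            y = 0.5 * (y + y0_base)
            continue
        g = y - y0_base - pre * f
        if np.max(np.abs(g) / scale) < tol:
            return y
        step = np.zeros(d)
        for i in range(d):
            if g[i] == 0.0:
                continue
            hj = 1e-7 * max(1.0, abs(y[i]))
            yp = y.copy()
            yp[i] += hj
            try:
                fp = np.asarray(rhs(t, yp), dtype=float)
                dfi = (fp[i] - f[i]) / hj if np.isfinite(fp[i]) else 0.0
            except FloatingPointError:
                dfi = 0.0
            denom = 1.0 - pre[i] * dfi
            if abs(denom) < 1e-8:
                denom = 1e-8 if denom >= 0 else -1e-8
            step[i] = -g[i] / denom
        y = y + step
    return y


def abm_solve(rhs, v, init, horizon: float, N: int = 4096,
              corrector_sweeps: int = 1,
              corrector: str = "newton") -> StateTrajectory:
    """Integrate D^{v_i} y_i = rhs(t, y)_i on [0, horizon] with N steps.

    Parameters
    ----------
    rhs
        Callable ``rhs(t, y) -> array`` of the same length as the state.
    v
        Scalar order, per-component order vector, or FractionalOrders.
    init
        Initial state (array-like or InitialState).
    N
        Step count; the grid has N+1 points.
    corrector_sweeps
        Number of functional corrector applications per step (>= 1), used
        when ``corrector='sweeps'``.
    corrector
        ``'newton'`` (default) solves the Adams-Moulton corrector equation
        implicitly, which keeps the scheme stable on stiff right-hand
        sides; ``'sweeps'`` is the classical explicit PECE variant.
    """
    from .model import InitialState

    if isinstance(init, InitialState):
        y0 = init.as_array()
    else:
        y0 = np.atleast_1d(np.asarray(init, dtype=float))
    d = y0.size
    orders = _orders_array(v, d)
    if N < 2:
        raise ValueError("N must be >= 2")
    if corrector_sweeps < 1:
        raise ValueError("corrector_sweeps must be >= 1")
    if corrector not in ("newton", "sweeps"):
        raise ValueError("corrector must be 'newton' or 'sweeps'")
    h = horizon / N
    times = np.linspace(0.0, horizon, N + 1)

    # Per-component weight tables.  Predictor: b_k = k^v - (k-1)^v,
    # k = 1..N; corrector interior: a_k = (k+1)^{v+1} + (k-1)^{v+1}
    # - 2 k^{v+1}, k = 1..N-? (index k = n+1-j).
    k = np.arange(0, N + 2, dtype=float)
    bw = np.empty((d, N + 1))   # bw[i][k-1] = b_k = k^v - (k-1)^v, k = 1..N+1
    aw = np.empty((d, N))       # aw[i][k-1] = a_k, k = 1..N (interior weights)
    for i in range(d):
        vi = orders[i]
        kp = k ** vi
        kp1 = k ** (vi + 1.0)
        bw[i] = kp[1:] - kp[:-1]
        aw[i] = kp1[2:N + 2] + kp1[0:N] - 2.0 * kp1[1:N + 1]
    # the j = 0 corrector weight depends on n; computed in the loop.
    pre_pred = h ** orders / _gamma(orders + 1.0)
    pre_corr = h ** orders / _gamma(orders + 2.0)

    states = np.empty((N + 1, d))
    states[0] = y0
    F = np.empty((N + 1, d))
    F[0] = np.asarray(rhs(0.0, y0), dtype=float)

    # O(N) running memory sums for integer-order components (all fractional
    # Adams weights are then constant: b_k = 1, interior a_k = 2, a_0 = 1).
    is_one = orders == 1.0
    run_pred = F[0].copy()           # sum_{j<=n} f_j
    run_corr = np.zeros(d)           # 2 * sum_{1<=j<=n} f_j

    for n in range(N):
        t_next = times[n + 1]
        hist = F[: n + 1]                            # f_0 .. f_n
        pred = np.empty(d)
        corr_mem = np.empty(d)
        for i in range(d):
            vi = orders[i]
            if is_one[i]:
                pred[i] = run_pred[i]
                corr_mem[i] = run_corr[i] + hist[0, i]
                continue
            # predictor memory: sum_j b_{n+1-j} f_j
            pred[i] = np.dot(bw[i][: n + 1][::-1], hist[:, i])
            # corrector memory over j = 1..n (k = n+1-j = 1..n)
            if n >= 1:
                corr_mem[i] = np.dot(aw[i][:n][::-1], hist[1: n + 1, i])
            else:
                corr_mem[i] = 0.0
            a0 = n ** (vi + 1.0) - (n - vi) * (n + 1) ** vi
            corr_mem[i] += a0 * hist[0, i]
        y_pred = y0 + pre_pred * pred
        if corrector == "newton":
            base = y0 + pre_corr * corr_mem
            y_new = _newton_corrector(rhs, t_next, base, pre_corr, y_pred)
        else:
            y_new = y_pred
            for _ in range(corrector_sweeps):
                f_new = np.asarray(rhs(t_next, y_new), dtype=float)
                y_new = y0 + pre_corr * (corr_mem + f_new)
        if not np.all(np.isfinite(y_new)):
            partial = StateTrajectory(times[: n + 1], states[: n + 1],
                                      orders, step_count=n)
            raise SolverFailure(
                f"non-finite state at step {n + 1} (t = {t_next:g})",
                last_valid_index=n, partial=partial)
        states[n + 1] = y_new
        try:
            F[n + 1] = np.asarray(rhs(t_next, y_new), dtype=float)
        except FloatingPointError as exc:
            partial = StateTrajectory(times[: n + 2], states[: n + 2],
                                      orders, step_count=n + 1)
            raise SolverFailure(
                f"right-hand side overflow at step {n + 1} (t = {t_next:g})",
                last_valid_index=n + 1, partial=partial) from exc
        run_pred += F[n + 1]
        run_corr += 2.0 * F[n + 1]

    return StateTrajectory(times=times, states=states, orders=orders,
                           step_count=N)


_ML_OVERFLOW = 200.0


def mittag_leffler(alpha: float, z: float) -> float:
    """One-parameter Mittag-Leffler function E_alpha(z) for alpha in (0, 1].

    Evaluated by the defining series in extended precision (mpmath); for
    large negative arguments the algebraic asymptotic expansion
    -sum_k z^{-k} / Gamma(1 - alpha k) is used instead.  E_1 = exp.
    """
    import mpmath as mp

    alpha = float(alpha)
    z = float(z)
    if not 0.0 < alpha <= 1.0:
        raise ValueError("alpha must lie in (0, 1]")
    if abs(z) > _ML_OVERFLOW:
        if z > 0:
            raise ValueError(f"argument {z} exceeds the overflow guard")
        # asymptotic series, truncated at its smallest term
        total, term_prev = 0.0, np.inf
        for kk in range(1, 60):
            g = _gamma(1.0 - alpha * kk)
            if not np.isfinite(g) or g == 0.0:
                continue
            term = -(z ** (-kk)) / g
            if abs(term) > term_prev:
                break
            total += term
            term_prev = abs(term)
        return float(total)
    with mp.workdps(50):
        s = mp.nsum(lambda kk: mp.mpf(z) ** kk / mp.gamma(alpha * kk + 1),
                    [0, mp.inf])
        return float(s)
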