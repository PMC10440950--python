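"""Fractional tumor-immune interaction model for lung cancer.

Four coupled Caputo equations for the densities of tumor cells T, active
macrophages A, macrophages M and normal host cells W:

    D^v1 T = d2^v1 T (1 - T/l2^v1) - theta^v1 T A - alpha1^v1 W T
    D^v2 A = rho1^v2 M A - h2^v2 A
    D^v3 M = d1^v3 M (1 - M/l1^v3) - rho2^v3 M A - h1^v3 M
    D^v4 W = d3^v4 W (1 - W/l3^v4) - alpha2^v4 W T

Each rate constant is raised to the power of its equation's fractional
order, which keeps the units of every term at cells/day^v.  Tumor and
macrophage populations grow logistically toward their carrying capacities
l2 and l1; host cells are depleted through competition with the tumor
(alpha2), and tumor growth is checked by active macrophages (theta) and by
competition with host cells (alpha1).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

__all__ = [
    "ModelParameters",
    "FractionalOrders",
    "InitialState",
    "StateVector",
    "default_parameters",
    "default_initial_state",
    "powered_parameters",
    "rhs",
    "equilibria",
    "positivity_monitor",
]


@dataclass(frozen=True)
class ModelParameters:
    """Model rate constants; defaults are the published fit for lung cancer.

    Units: rho1, rho2, alpha1, alpha2, theta in (cell day)^-1; d1, d2, d3,
    h1, h2 in day^-1; carrying capacities l1, l2, l3 in cells.
    """

    rho1: float = 0.0937
    rho2: float = 0.0122
    d1: float = 0.9000
    d2: float = 0.5045
    d3: float = 0.6169
    alpha1: float = 4.3930e-14
    alpha2: float = 0.7609
    h1: float = 4.3884e-14
    h2: float = 0.8809
    theta: float = 0.0140
    l1: float = 5.0785e7
    l2: float = 2.7785e5
    l3: float = 5.4621e6

    def __post_init__(self) -> None:
        for name in ("rho1", "rho2", "d1", "d2", "d3", "alpha1", "alpha2",
                     "h1", "h2", "theta"):
            if getattr(self, name) < 0:
                raise ValueError(f"parameter {name} must be nonnegative")
        for name in ("l1", "l2", "l3"):
            if getattr(self, name) <= 0:
                raise ValueError(f"carrying capacity {name} must be positive")

    def with_overrides(self, **kwargs) -> "ModelParameters":
        return replace(self, **kwargs)


@dataclass(frozen=True)
class FractionalOrders:
    """Per-equation Caputo orders v1..v4, each in (0, 1]."""

    v1: float = 1.0
    v2: float = 1.0
    v3: float = 1.0
    v4: float = 1.0

    def __post_init__(self) -> None:
        for name in ("v1", "v2", "v3", "v4"):
            v = float(getattr(self, name))
            if not 0.0 < v <= 1.0:
                raise ValueError(f"order {name} must lie in (0, 1], got {v}")
            object.__setattr__(self, name, v)

    @classmethod
    def uniform(cls, v: float) -> "FractionalOrders":
        return cls(v, v, v, v)

    def as_array(self) -> np.ndarray:
        return np.array([self.v1, self.v2, self.v3, self.v4])


@dataclass(frozen=True)
class InitialState:
    """Initial cell densities (all nonnegative)."""

    T0: float = 5.0
    A0: float = 0.0
    M0: float = 20.0
    W0: float = 200.0

    def __post_init__(self) -> None:
        for name in ("T0", "A0", "M0", "W0"):
            if getattr(self, name) < 0:
                raise ValueError(f"initial value {name} must be nonnegative")

    def as_array(self) -> np.ndarray:
        return np.array([self.T0, self.A0, self.M0, self.W0])


@dataclass(frozen=True)
class StateVector:
    """A model state (T, A, M, W) in cells."""

    T: float
    A: float
    M: float
    W: float

    def as_array(self) -> np.ndarray:
        return np.array([self.T, self.A, self.M, self.W])


def default_parameters() -> ModelParameters:
    """The published parameter set (lung-cancer fit)."""
    return ModelParameters()


def default_initial_state() -> InitialState:
    """The published simulation initial conditions (5, 0, 20, 200)."""
    return InitialState()


def powered_parameters(p: ModelParameters, v: FractionalOrders) -> dict:
    """Every rate constant raised to its equation's fractional order."""
    return {
        "d2": p.d2 ** v.v1, "l2": p.l2 ** v.v1,
        "theta": p.theta ** v.v1, "alpha1": p.alpha1 ** v.v1,
        "rho1": p.rho1 ** v.v2, "h2": p.h2 ** v.v2,
        "d1": p.d1 ** v.v3, "l1": p.l1 ** v.v3,
        "rho2": p.rho2 ** v.v3, "h1": p.h1 ** v.v3,
        "d3": p.d3 ** v.v4, "l3": p.l3 ** v.v4,
        "alpha2": p.alpha2 ** v.v4,
    }


def rhs(state, p: ModelParameters, v: FractionalOrders) -> np.ndarray:
    """Right-hand side of the four Caputo equations at a state (T, A, M, W).

    Accepts a StateVector or any length-4 array-like; broadcasting over
    trailing axes is supported so trajectories can be evaluated in one call.
    """
    if isinstance(state, StateVector):
        state = state.as_array()
    state = np.asarray(state, dtype=float)
    T, A, M, W = state[0], state[1], state[2], state[3]
    q = powered_parameters(p, v)
    out = np.empty_like(state)
    out[0] = q["d2"] * T * (1.0 - T / q["l2"]) - q["theta"] * T * A - q["alpha1"] * W * T
    out[1] = q["rho1"] * M * A - q["h2"] * A
    out[2] = q["d1"] * M * (1.0 - M / q["l1"]) - q["rho2"] * M * A - q["h1"] * M
    out[3] = q["d3"] * W * (1.0 - W / q["l3"]) - q["alpha2"] * W * T
    if not np.all(np.isfinite(out)):
        raise FloatingPointError("model right-hand side overflowed")
    return out


def equilibria(p: ModelParameters, v: FractionalOrders) -> list[StateVector]:
    """Closed-form coordinate equilibria (diagnostic).

    Returns the origin, the single-population fixed points, and the
    linearly solvable pairwise combinations, each verified numerically
    against the right-hand side.
    """
    q = powered_parameters(p, v)
    candidates: list[np.ndarray] = [np.zeros(4)]

    # Single-population branches (others zero).
    if q["d2"] > 0:
        candidates.append(np.array([q["l2"], 0.0, 0.0, 0.0]))
    if q["d1"] > 0:
        m_star = q["l1"] * (1.0 - q["h1"] / q["d1"])
        if m_star > 0:
            candidates.append(np.array([0.0, 0.0, m_star, 0.0]))
    if q["d3"] > 0:
        candidates.append(np.array([0.0, 0.0, 0.0, q["l3"]]))

    # T-W coexistence (A = M = 0): linear 2x2 system in (T, W).
    if q["d2"] > 0 and q["d3"] > 0:
        a = np.array([
            [q["d2"] / q["l2"], q["alpha1"]],
            [q["alpha2"], q["d3"] / q["l3"]],
        ])
        b = np.array([q["d2"], q["d3"]])
        try:
            tw = np.linalg.solve(a, b)
            if np.all(tw > 0):
                candidates.append(np.array([tw[0], 0.0, 0.0, tw[1]]))
        except np.linalg.LinAlgError:
            pass

    # M-W (decoupled) coexistence.
    if q["d1"] > 0 and q["d3"] > 0:
        m_star = q["l1"] * (1.0 - q["h1"] / q["d1"])
        if m_star > 0:
            candidates.append(np.array([0.0, 0.0, m_star, q["l3"]]))

    # A-M coexistence (T = W = 0): M pinned by the A-equation, A from M's.
    if q["rho1"] > 0:
        m_star = q["h2"] / q["rho1"]
        if q["rho2"] > 0:
            a_star = (q["d1"] * (1.0 - m_star / q["l1"]) - q["h1"]) / q["rho2"]
            if a_star > 0:
                candidates.append(np.array([0.0, a_star, m_star, 0.0]))

    out = []
    seen = set()
    for c in candidates:
        key = tuple(np.round(c, 6))
        if key in seen:
            continue
        seen.add(key)
        resid = np.max(np.abs(rhs(c, p, v)))
        if resid < 1e-8 * (1.0 + np.linalg.norm(c)):
            out.append(StateVector(*c))
    return out


def positivity_monitor(states: np.ndarray, scales=None, tol: float = 1e-6):
    """Flag negative excursions beyond -tol * scale per component.

    ``states`` is (4, n) or (n, 4); returns a length-4 boolean array, True
    where the component dips below the tolerated excursion.  No clamping is
    performed: overshoot is reported, never hidden.
    """
    arr = np.asarray(states, dtype=float)
    if arr.ndim == 1:
        arr = arr[:, None]
    if arr.shape[0] != 4:
        arr = arr.T
    if scales is None:
        scales = np.maximum(1.0, np.max(np.abs(arr), axis=1))
    scales = np.asarray(scales, dtype=float)
    return np.min(arr, axis=1) < -tol * scales
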