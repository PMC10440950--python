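"""Run configuration: YAML schema, validation, defaults.

A run is fully described by a flat YAML document; every key is optional and
defaults to the published study setup (lung-cancer parameter table, initial
state (5, 0, 20, 200), horizon 150 days, basis sizes (4, 4, 6, 5)).
Unknown keys are rejected by name — a silently ignored typo in a parameter
name would corrupt the science.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, replace

import yaml

from .model import (FractionalOrders, InitialState, ModelParameters,
                    default_initial_state, default_parameters)
from .optimize import SolverConfig

__all__ = ["RunConfig", "load_config", "config_from_mapping"]

_PARAM_KEYS = {"rho1", "rho2", "d1", "d2", "d3", "alpha1", "alpha2",
               "h1", "h2", "theta", "l1", "l2", "l3"}
_INIT_KEYS = {"T0", "A0", "M0", "W0"}
_SOLVER_KEYS = {"mode", "multistarts", "seed", "exponent_upper",
                "optimize_exponents", "gradient_tol", "constraint_tol",
                "max_iterations", "reference_steps"}
_TOP_KEYS = {"parameters", "initial_state", "orders", "horizon",
             "basis_sizes", "node_count", "solver", "paper_mode",
             "report_points", "output_dir", "seed", "reference_comparison"}


@dataclass(frozen=True)
class RunConfig:
    """Validated settings for one solver run."""

    parameters: ModelParameters = field(default_factory=default_parameters)
    initial_state: InitialState = field(default_factory=default_initial_state)
    orders: FractionalOrders = field(default_factory=FractionalOrders)
    horizon: float = 150.0
    basis_sizes: tuple = (4, 4, 6, 5)
    node_count: int = 64
    solver: SolverConfig = field(default_factory=SolverConfig)
    paper_mode: bool = False        # True: literal frame, no normalization
    report_points: int = 301
    output_dir: str = "runs"
    seed: int = 0
    reference_comparison: bool = False

    def __post_init__(self) -> None:
        if self.horizon <= 0:
            raise ValueError("horizon must be positive")
        if len(self.basis_sizes) != 4 or any(m < 1 for m in self.basis_sizes):
            raise ValueError("basis_sizes must be four integers >= 1")
        if self.report_points < 2:
            raise ValueError("report_points must be >= 2")

    def echo(self) -> dict:
        """Plain-dict rendering of the effective configuration."""
        d = {
            "parameters": asdict(self.parameters),
            "initial_state": asdict(self.initial_state),
            "orders": asdict(self.orders),
            "horizon": self.horizon,
            "basis_sizes": list(self.basis_sizes),
            "node_count": self.node_count,
            "solver": asdict(self.solver),
            "paper_mode": self.paper_mode,
            "report_points": self.report_points,
            "output_dir": self.output_dir,
            "seed": self.seed,
            "reference_comparison": self.reference_comparison,
        }
        d["solver"].pop("exponent_bounds", None)
        return d


def _check_keys(mapping: dict, allowed: set, context: str) -> None:
    unknown = set(mapping) - allowed
    if unknown:
        names = ", ".join(sorted(unknown))
        raise ValueError(f"unknown {context} key(s): {names}")


def config_from_mapping(doc: dict | None) -> RunConfig:
    """Build and validate a RunConfig from a parsed YAML mapping."""
    if doc is None:
        doc = {}
    if not isinstance(doc, dict):
        raise ValueError("configuration root must be a mapping")
    _check_keys(doc, _TOP_KEYS, "configuration")

    params = default_parameters()
    if "parameters" in doc:
        sub = doc["parameters"] or {}
        _check_keys(sub, _PARAM_KEYS, "parameters")
        params = params.with_overrides(**{k: float(x) for k, x in sub.items()})

    init = default_initial_state()
    if "initial_state" in doc:
        sub = doc["initial_state"] or {}
        _check_keys(sub, _INIT_KEYS, "initial_state")
        init = replace(init, **{k: float(x) for k, x in sub.items()})

    orders = FractionalOrders()
    if "orders" in doc:
        sub = doc["orders"]
        if isinstance(sub, dict):
            _check_keys(sub, {"v1", "v2", "v3", "v4"}, "orders")
            orders = FractionalOrders(**{k: float(x) for k, x in sub.items()})
        else:
            vals = [float(x) for x in sub]
            if len(vals) == 1:
                orders = FractionalOrders.uniform(vals[0])
            elif len(vals) == 4:
                orders = FractionalOrders(*vals)
            else:
                raise ValueError("orders must have one or four entries")

    solver = SolverConfig()
    if "solver" in doc:
        sub = doc["solver"] or {}
        _check_keys(sub, _SOLVER_KEYS, "solver")
        solver = replace(solver, **sub)

    kwargs = {}
    for key in ("horizon", "node_count", "paper_mode", "report_points",
                "output_dir", "seed", "reference_comparison"):
        if key in doc:
            kwargs[key] = doc[key]
    if "basis_sizes" in doc:
        kwargs["basis_sizes"] = tuple(int(m) for m in doc["basis_sizes"])
    return RunConfig(parameters=params, initial_state=init, orders=orders,
                     solver=solver, **kwargs)


def load_config(path) -> RunConfig:
    """Parse and validate a YAML configuration file (empty file = defaults)."""
    with open(path, "r", encoding="utf-8") as fh:
        doc = yaml.safe_load(fh)
    return config_from_mapping(doc)
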