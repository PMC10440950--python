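"""Run orchestration: solver runs, reference simulations, exports, reports.

Everything a run produces is written as plain text: the trajectory as a
CSV with header ``t,T,A,M,W`` on a uniform report grid, and a JSON report
carrying the effective configuration, the optimized coefficients and
exponents, the objective in both frames, qualitative monotonicity flags,
and timing.  Runs are deterministic under a fixed seed, and the config echo
makes every report self-describing.
"""

from __future__ import annotations

import json
import time
from dataclasses import replace
from pathlib import Path

import numpy as np
import pandas as pd

from .config import RunConfig
from .model import positivity_monitor, rhs
from .optimize import SolveResult, SolverConfig, SpectralProblem, solve
from .reference import StateTrajectory, abm_solve

__all__ = [
    "run_model",
    "simulate_reference",
    "compare_run",
    "export_trajectory",
    "monotonicity_flags",
    "report_grid",
]

_CSV_COLUMNS = ("t", "T", "A", "M", "W")


def report_grid(cfg: RunConfig) -> np.ndarray:
    return np.linspace(0.0, cfg.horizon, cfg.report_points)


def monotonicity_flags(times: np.ndarray, states: np.ndarray,
                       a_scale: float = 1.0) -> dict:
    """Qualitative trajectory descriptors on a report grid.

    T is expected to increase steadily and W to decline after its first
    step in the published scenario; A stays identically zero when it starts
    at zero.  Small tolerances absorb roundoff, not model behaviour.
    """
    T, A, W = states[:, 0], states[:, 1], states[:, 3]
    tol_T = 1e-9 * max(1.0, float(np.max(np.abs(T))))
    tol_W = 1e-9 * max(1.0, float(np.max(np.abs(W))))
    return {
        "T_nondecreasing": bool(np.all(np.diff(T) >= -tol_T)),
        "W_nonincreasing_after_first_step": bool(np.all(np.diff(W[1:]) <= tol_W)),
        "A_max_abs_over_scale": float(np.max(np.abs(A)) / max(a_scale, 1e-300)),
        "negative_excursions": positivity_monitor(states.T).tolist(),
    }


def export_trajectory(times, states, path) -> Path:
    """Write a ``t,T,A,M,W`` CSV at full double precision."""
    times = np.asarray(times, dtype=float)
    states = np.asarray(states, dtype=float)
    if states.shape != (times.size, 4):
        raise ValueError("states must have shape (len(times), 4)")
    df = pd.DataFrame(
        {c: col for c, col in zip(_CSV_COLUMNS,
                                  [times] + [states[:, i] for i in range(4)])})
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False, float_format="%.17g")
    return path


def _problem_from_config(cfg: RunConfig) -> SpectralProblem:
    return SpectralProblem(
        params=cfg.parameters, orders=cfg.orders, init=cfg.initial_state,
        horizon=cfg.horizon, sizes=cfg.basis_sizes,
        node_count=cfg.node_count, normalized=not cfg.paper_mode,
    )


def run_model(cfg: RunConfig, output_dir=None) -> SolveResult:
    """Full spectral-optimization run with CSV/JSON outputs.

    Outputs land in ``output_dir`` (default from the config): trajectory.csv,
    report.json, and reference.csv when a side-by-side predictor-corrector
    run is requested.  On solver failure the outputs are still written, with
    a failure marker in the report.
    """
    out = Path(output_dir if output_dir is not None else cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    solver_cfg = replace(cfg.solver, seed=cfg.seed)
    problem = _problem_from_config(cfg)
    t0 = time.perf_counter()
    result = solve(problem, solver_cfg)
    wall = time.perf_counter() - t0

    grid = report_grid(cfg)
    states = result.sample(grid)
    export_trajectory(grid, states, out / "trajectory.csv")

    a_scale = max(1.0, cfg.initial_state.A0)
    report = {
        "config": cfg.echo(),
        "success": result.success,
        "message": result.message,
        "objective_frame": result.objective,
        "objective_literal": result.literal_objective,
        "constraint_residual": result.constraint_residual,
        "coefficients": [c.tolist() for c in result.coefficients],
        "exponents": [b.tolist() for b in result.exponents],
        "multipliers": (None if result.multipliers is None
                        else list(result.multipliers)),
        "wall_time_s": wall,
        "flags": monotonicity_flags(grid, states, a_scale),
        "diagnostics": result.diagnostics,
    }
    if cfg.reference_comparison:
        ref = simulate_reference(cfg)
        ref_states = ref.sample(grid)
        export_trajectory(grid, ref_states, out / "reference.csv")
        scales = problem.frame().state_scales
        report["reference_discrepancy"] = {
            "normalized_sup": float(np.max(np.abs(states - ref_states) / scales)),
            "per_state_sup": (np.max(np.abs(states - ref_states), axis=0)
                              / scales).tolist(),
        }
    with open(out / "report.json", "w", encoding="utf-8") as fh:
        json.dump(report, fh, indent=2)
    return result


def simulate_reference(cfg: RunConfig, steps: int = 4096) -> StateTrajectory:
    """Predictor-corrector run of the configured model (no spectral solve)."""
    p, v = cfg.parameters, cfg.orders
    return abm_solve(lambda t, y: rhs(y, p, v), v, cfg.initial_state,
                     cfg.horizon, N=steps)


def compare_run(cfg: RunConfig, output_dir=None, steps: int = 4096) -> dict:
    """Spectral fit and reference run side by side, with a discrepancy table."""
    cfg = replace(cfg, reference_comparison=True)
    out = Path(output_dir if output_dir is not None else cfg.output_dir)
    result = run_model(cfg, out)
    with open(out / "report.json", "r", encoding="utf-8") as fh:
        report = json.load(fh)
    return {
        "success": result.success,
        "objective_frame": result.objective,
        "discrepancy": report.get("reference_discrepancy"),
    }
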