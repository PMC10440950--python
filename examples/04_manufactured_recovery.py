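"""Method-of-manufactured-solutions verification of the spectral solver.

A known solution is planted in the GLP span; the residual minimizer must
drive the objective to zero and recover every coefficient.
"""
import numpy as np

from fraclag import FractionalOrders, SolverConfig, make_manufactured_problem, solve
from fraclag.optimize import multistart_schedule

v = FractionalOrders(0.7, 0.9, 0.8, 1.0)
mp = make_manufactured_problem(seed=3, v=v, sizes=(3, 3, 4, 4))
prob = mp.spectral_problem()
cfg = SolverConfig(optimize_exponents=False, multistarts=2, seed=0)
base = multistart_schedule(0, 2, cfg.bounds_for(prob.sizes), prob)
starts = [(c, [np.array(b) for b in mp.exponents]) for c, _ in base]
res = solve(prob, cfg, starts=starts)
err = max(np.max(np.abs(c - t)) for c, t in zip(res.coefficients,
                                                mp.target_coefficients))
print(f"objective Q* = {res.objective:.3e}  (zero up to roundoff)")
print(f"max coefficient recovery error = {err:.3e}")
print(f"initial-condition defect = {res.constraint_residual:.1e}")
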