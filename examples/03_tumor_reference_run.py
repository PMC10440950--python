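"""Reference predictor-corrector runs of the tumor-immune model.

Simulates 150 days at several uniform Caputo orders and prints the endpoint
densities together with the qualitative flags: tumor cells rise steadily,
host cells decline after their first step, active macrophages stay at zero
because they start at zero.
"""
import numpy as np

from fraclag import FractionalOrders, abm_solve, default_initial_state, default_parameters, rhs

p = default_parameters()
init = default_initial_state()
grid = np.linspace(0.0, 150.0, 301)
print("order   T(150)      M(150)      W_min     T rising  W falling")
for vv in (0.70, 0.80, 0.90, 1.00):
    v = FractionalOrders.uniform(vv)
    traj = abm_solve(lambda t, y: rhs(y, p, v), v, init, 150.0, N=2048)
    S = traj.sample(grid)
    rising = bool(np.all(np.diff(S[:, 0]) >= -1e-9 * S[:, 0].max()))
    falling = bool(np.all(np.diff(S[1:, 3]) <= 1e-9 * S[:, 3].max()))
    print(f"{vv:4.2f}  {S[-1,0]:11.4g} {S[-1,2]:11.4g} {S[:,3].min():9.3g}"
          f"   {rising!s:5}     {falling!s:5}")
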