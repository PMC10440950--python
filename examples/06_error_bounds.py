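"""Desk-scale error-bound diagnostics for truncated expansions."""
from fraclag import best_approx_bound, caputo_error_bound, truncation_tail_bound
from fraclag.bounds import glp_sup

M3 = glp_sup(3)
print(f"sup |L_3| on [0,1] = {M3:.6f}")
print("tail bound, dropped coefficients (0.1, -0.2), M = 2:",
      truncation_tail_bound([0.1, -0.2], 2.0))
# fitting t^5 with a cubic: L = sup |d^4 t^5/dt^4| = 120, expansion point 1/2
print(f"best-approximation bound (L=120, m=3, t0=0.5): "
      f"{best_approx_bound(120.0, M3, 0.5, 3):.6f}")
print(f"Caputo image of the unit bound (m=2, n=1, v=0.5): "
      f"{caputo_error_bound(1.0, 1.0, 1.0, 2, 1, 0.5):.7f}")
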