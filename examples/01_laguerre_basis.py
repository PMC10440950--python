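"""Build the Laguerre coefficient matrix and evaluate generalized polynomials.

The lower-triangular matrix row m holds the monomial coefficients of the
degree-m polynomial; free exponents beta_k swap the monomials t^k for
t^{k+beta_k} without touching the coefficients.
"""
import numpy as np

from fraclag import BasisSpec, build_coefficient_matrix, evaluate_glp

D = build_coefficient_matrix(3)
print("6 * L_3 coefficients (1, t, t^2, t^3):", (6 * D.row(3)).tolist())
print("2 * L_2 coefficients:", (2 * build_coefficient_matrix(2).row(2)).tolist())

# classical value L_2(2) = (4 - 8 + 2)/2 = -1
print("L_2(2) =", evaluate_glp(2, 0.0, 2.0))

# a generalized family: exponents (0.5, 0) makes the first monomial t^{1.5}
spec = BasisSpec(size=2, exponents=[0.5, 0.0])
print("monomial powers with beta = (0.5, 0):", spec.powers.tolist())
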