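"""Caputo derivatives of power functions and GLP series, with oracle check.

The operational route (diagonal gamma-ratio factors) is compared against an
independent L1 discretization of the convolution integral.
"""
import numpy as np

from fraclag import (ApproximantSeries, BasisSpec, caputo_derivative_series,
                     caputo_power, gl_caputo_oracle)

res = caputo_power(1.0, 0.5)
print(f"D^0.5 t = {res.coefficient:.7f} * t^{res.exponent}")

# series representing t^{1.5}; its half-derivative is Gamma(2.5)/Gamma(2) * t
spec = BasisSpec(size=1, exponents=[0.5])
s = ApproximantSeries.from_coefficients([1.0, -1.0], spec)
val = caputo_derivative_series(s, 0.5, 2.0)
oracle = gl_caputo_oracle(lambda t: np.asarray(t) ** 1.5, 0.5, 2.0, steps=100_000)
print(f"D^0.5 t^1.5 at t=2: operational {val:.7f}, L1 oracle {oracle:.7f}")
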