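"""Calibrate the parametric stiffness law k = alpha * H * (t/D)^3 * E.

Runs a small FEM sweep (2 values per parameter here, to stay quick; the
full calibration uses 3+) over cylinder height, diameter, wall thickness
and modulus, fits alpha by least squares and reports the goodness of fit.
"""

import numpy as np

from morphoforce import fit_alpha, run_sweep

H = [20.0, 100.0]
D = [140.0, 220.0]
t = [5.0, 25.0]
E = [5.0, 80.0]       # kPa

records = run_sweep(H, D, t, E)           # 16 ring solves
fit = fit_alpha(records)

ks = np.array([r.k for r in records])
print(f"{len(records)} sweep cells, k from {ks.min():.3g} to {ks.max():.3g} nN/um")
print(f"alpha = {fit.alpha:.3f}   R^2 = {fit.r_squared:.5f}   "
      f"worst relative residual = {fit.max_rel_residual:.1%}")
print("alpha condenses every geometry/stiffness combination into one "
      "constant: measure a sensor's dimensions and modulus, multiply, and "
      "its nN-per-um conversion factor follows without new simulations.")
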