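"""Estimate the hydrogel Young's modulus from an AFM indentation curve.

Synthesizes a pyramidal-tip force curve at 1% noise and fits the Hertz
contact model (four-sided pyramid, nu = 0.5) with joint contact-point
estimation.
"""

from morphoforce import fit_hertz_pyramidal
from morphoforce.synthetic import make_afm_curve

curve, truth = make_afm_curve(E=80.0, theta=20.0, contact_point=0.15,
                              noise=0.01, seed=11)
fit = fit_hertz_pyramidal(curve, nu=0.5)

print(f"true modulus      : {truth['E']:.1f} kPa "
      f"(contact point {truth['contact_point']:.2f} um)")
print(f"fitted modulus    : {fit.E_est:.1f} kPa "
      f"(contact point {fit.contact_point:.2f} um)")
print(f"rms force residual: {fit.rms_residual:.3f} nN")
print("This is the modulus E that enters the stiffness law; the sensors "
      "hold it stably for weeks, which is what makes the calibration "
      "trustworthy over a live-imaging session.")
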