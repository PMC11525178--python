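"""Full image-to-force pipeline on a synthetic time-lapse.

Renders a drifting, noisy movie of the deforming sensor annulus, registers
and segments it, measures the bounding-rectangle width per frame and
converts the trace to force — then compares against the scripted ground
truth the movie was rendered from.
"""

import numpy as np

from morphoforce import extract_trace, infer_profile
from morphoforce.synthetic import TrajectoryParams, make_trajectory, render_movie

trace_in, truth = make_trajectory(
    TrajectoryParams(s_max=8.0, tau=40.0, noise_sd=0.0),
    times=np.arange(0.0, 241.0, 30.0))

stack, _ = render_movie(trace_in, pixel_size=0.59, photons_peak=200.0,
                        drift_per_frame=(0.4, 0.3), seed=123)
print(f"rendered {stack.n_frames} frames of {stack.frames.shape[1:]} px "
      f"at {stack.pixel_size} um/px with stage drift and shot noise")

trace = extract_trace(stack)                     # register -> segment -> measure
profile = infer_profile(trace, truth["k"])

err = np.abs(profile.force - truth["force_nN"])
print("true force (nN)     :", np.round(truth["force_nN"], 1))
print("recovered force (nN):", np.round(profile.force, 1))
print(f"worst absolute error: {err.max():.1f} nN "
      f"({err[1:].max() / truth['force_nN'][1:].max():.1%} of the plateau)")
print("Sub-pixel registration plus bounding-rectangle width keeps the "
      "recovered forces within a few nN of truth despite drift and noise.")
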