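"""Cohort force profiles and a two-group comparison.

Builds two cohorts of n = 10 embryos: vehicle-like (compressing sensors)
and ROCK-inhibited-like (widening sensors), summarizes each as mean +- 95%
CI over time, and compares their maximum 60-min impulses with a two-tailed
t-test.
"""

import numpy as np

from morphoforce import cohort_profile, compare_groups, infer_profile, max_impulse
from morphoforce.synthetic import CohortParams, TrajectoryParams, make_cohort

times = np.arange(0.0, 601.0, 30.0)
K = 7.15

vehicle, _ = make_cohort(CohortParams(n=10, variability=0.15, seed=1),
                         TrajectoryParams(s_max=8.0, noise_sd=0.6),
                         times=times)
rock, _ = make_cohort(CohortParams(n=10, variability=0.15, seed=2),
                      TrajectoryParams(s_max=4.0, tau=120.0, noise_sd=0.6,
                                       mode="widening"),
                      times=times)

veh_profiles = [infer_profile(t, K) for t in vehicle]
rock_profiles = [infer_profile(t, K) for t in rock]

summary = cohort_profile(veh_profiles)
print("vehicle cohort, mean force +- 95% CI (nN):")
for i in range(0, len(times), 5):
    print(f"  t={times[i]:4.0f} min: {summary.mean[i]:6.1f} "
          f"[{summary.ci_low[i]:6.1f}, {summary.ci_high[i]:6.1f}]  n={summary.n[i]}")

imp_v = [max_impulse(p) for p in veh_profiles]
imp_r = [max_impulse(p) for p in rock_profiles]
stat, p = compare_groups(imp_v, imp_r)
print(f"max 60-min impulse: vehicle {np.mean(imp_v):.0f} nN min, "
      f"ROCK-inhibited {np.mean(imp_r):.0f} nN min")
print(f"two-tailed t-test: t = {stat:.2f}, P = {p:.2g}")
print("Widening sensors carry negative force (the folds splay apart), and "
      "their slower force generation shows up as a significantly lower "
      "impulse - the comparison the impulse statistic was designed for.")
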