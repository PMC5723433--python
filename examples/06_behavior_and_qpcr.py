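"""Swim-track statistics and efficiency-corrected expression ratios.

Simulates wild-type and knockdown larval swim tracks with planted group
differences, summarizes per-fish distances, tests the groups with the
two-sample Kolmogorov-Smirnov test, and recovers planted expression ratios
from a simulated Ct table via the Pfaffl equation.
"""

import numpy as np

from captx import behavior, qpcr, synth

params = {"wt": {"speed": 0.23, "upper_bias": 0.5},
          "kd": {"speed": 0.03, "upper_bias": 0.1}}
tracks, _ = synth.gen_tracks({"wt": 41, "kd": 130}, params,
                             duration=60, fps=5, seed=0)
dist = {"wt": [], "kd": []}
upper = {"wt": [], "kd": []}
for t in tracks:
    dist[t.group].append(behavior.track_distance(t))
    upper[t.group].append(behavior.time_upper_half(t))

print(behavior.summarize(dist).to_string(index=False))
print("distance travelled (cm / 60 s) per group: the knockdown group is "
      "nearly stationary")
d, p = behavior.ks_two_sample(dist["kd"], dist["wt"], mode="asymptotic")
print(f"KS test kd vs wt: D = {d:.3f}, p = {p:.3g} "
      "(distribution-free evidence the groups differ)")
print(f"mean time in upper half: wt {np.mean(upper['wt']):.1f} s, "
      f"kd {np.mean(upper['kd']):.1f} s out of 60 s")

ratios = {"brain": 293.46, "gills": 68.70, "heart": 0.01}
table, _ = synth.gen_ct(ratios, noise_sd=0.2, n_replicates=3, seed=0)
out = qpcr.pfaffl_table(table, target="ca6", reference="gapdh",
                        calibrator="calibrator")
print("\nrelative expression recovered from the simulated Ct table:")
for _, row in out.iterrows():
    print(f"  {row['sample']:8s} ratio {row['ratio']:8.2f} "
          f"(truth {ratios[row['sample']]:8.2f})")
print("ratio = E_t^dCt_t / E_ref^dCt_ref with replicate Cts averaged first; "
      "Ct noise of 0.2 cycles moves ratios by up to ~30%")
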