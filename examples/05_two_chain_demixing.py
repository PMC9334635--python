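"""Polar organization of two chains as cavity anisotropy grows.

Simulates the two-blob surrogate of two equal dsDNA coils at low and high
eccentricity and prints the alignment order parameter, the pole-swap count
and the mean dwell time: anisotropy aligns the pair along the major axis
and slows pole swapping (the Kramers barrier grows with eccentricity).
"""

import numpy as np

from cavity_demix import TwoBlobConfig, make_cavity, simulate_two_blob_ensemble
from cavity_demix.trajectory_analysis import (
    detect_swaps,
    order_parameter,
    separation_series,
)

for e in (0.0, 0.6, 0.9):
    cavity = make_cavity(eccentricity=e, reference_radius=1.0, depth=0.2)
    config = TwoBlobConfig(cavity=cavity, seed=77, n_frames=2400)
    replicas = simulate_two_blob_ensemble(config, n_replicas=8)
    dwells, thetas, swaps = [], [], 0
    for t1, t2 in replicas:
        ss = separation_series(t1, t2, cavity)
        stats, n_sw = detect_swaps(ss)
        dwells.append(stats.dwell_samples)
        thetas.append(ss.theta)
        swaps += n_sw
    dw = np.concatenate(dwells)
    s_align = order_parameter(np.concatenate(thetas))
    tau = dw.mean() if len(dw) else float("nan")
    print(f"e = {e:.1f}: S_align = {s_align:5.2f}, swaps = {swaps:3d}, "
          f"mean dwell = {tau:5.1f} s (n = {len(dw)})")

print("\nS_align ~ 0 means free Brownian rotation of the pair; S_align -> 1 "
      "means the\nseparation vector locks onto the major axis. The dwell "
      "time grows with e as the\nwaist narrows and swapping requires "
      "squeezing past the partner chain.")
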