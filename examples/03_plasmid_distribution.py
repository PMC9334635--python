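"""Predicted plasmid position distribution in a chain-occupied cavity.

Combines chain exclusion (U = a * rho) with the boundary-integrated wall
repulsion, forms the Boltzmann map, and reports the wall-potential range
(where it reaches 2 kBT) and the radius of the resulting probability ring.
"""

import numpy as np

from cavity_demix import (
    ExclusionParams,
    KernelParams,
    boltzmann_distribution,
    exclusion_potential,
    make_cavity,
    range_at_threshold,
    solve_gsd,
    total_potential,
    wall_potential,
)

cavity = make_cavity(eccentricity=0.0, reference_radius=1.0, depth=0.2)
rho = solve_gsd(cavity)
kernel = KernelParams()          # exponential, 300 kBT/um, r_b = 50 nm
exclusion = ExclusionParams()    # a = 1.1e-6 kBT um^3/bp

wall = wall_potential(cavity, kernel, template=rho)
total = total_potential(exclusion_potential(rho, exclusion), wall)
prob = boltzmann_distribution(total)

d2 = range_at_threshold(cavity, kernel, threshold=2.0)
radii = np.linspace(0, 0.98, 50)
vals = prob.interpolate(np.column_stack([radii, np.zeros_like(radii)]))
ring = radii[np.argmax(vals)]

print(f"wall potential reaches 2 kBT at {1e3*d2:.0f} nm from the boundary")
print(f"plasmid probability peaks on a ring at r = {ring:.2f} um "
      f"(centre/max = {vals[0]/vals.max():.2f})")
print("\nThe ring is the segregation zone: outside it the wall repels the "
      "plasmid,\ninside it the chain's excluded volume does.")
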