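"""Mean-field concentration profile of a confined T4 DNA chain.

Solves the ground-state-dominance problem on an e = 0.6 cavity and prints
the chemical potential, the centre concentration and its enhancement over
the cavity-mean value: confinement piles the chain up in the middle,
leaving a depleted corona near the wall where a plasmid can live.
"""

import numpy as np

from cavity_demix import T4_DNA, concentration_at, make_cavity, solve_gsd

cavity = make_cavity(eccentricity=0.6, reference_radius=1.0, depth=0.2)
rho = solve_gsd(cavity)

mean_conc = T4_DNA.basepairs / (cavity.area * cavity.depth)
center = concentration_at(rho, np.array([0.0, 0.0]))

print(f"chain: {T4_DNA.basepairs} bp, {T4_DNA.n_kuhn:.0f} Kuhn segments")
print(f"solver: lambda = {rho.meta['lambda']:.5f}, "
      f"{rho.meta['iterations']} iterations, g = {rho.meta['g']}")
print(f"mean concentration   : {mean_conc:9.3g} bp/um^3")
print(f"centre concentration : {center:9.3g} bp/um^3 "
      f"({center / mean_conc:.2f}x the mean)")
print(f"total bp (integral)  : {rho.integrate() * cavity.depth:.1f}")
print("\nThe centre/mean ratio ~2 reflects the peaked ground-state profile; "
      "the profile\nvanishes at the wall (Dirichlet condition), which is what "
      "pushes the plasmid out.")
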