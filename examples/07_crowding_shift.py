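"""Macromolecular crowding displaces the plasmid distribution inward.

Applies the parameter-level crowding emulation (crowder volume fraction
6.3e-2) to the plasmid model in circular and e = 0.9 cavities, and
measures the inward shift of the 1/e edge of the contour-averaged density:
the effect is several-fold stronger in the anisotropic cavity.
"""

from cavity_demix import (
    ExclusionParams,
    KernelParams,
    boltzmann_distribution,
    exclusion_potential,
    make_cavity,
    make_crowded_variant,
    solve_gsd,
    total_potential,
    wall_potential,
)
from cavity_demix.trajectory_analysis import contour_profile, edge_shift

base_excl, base_kern = ExclusionParams(), KernelParams()
crowd_excl, crowd_kern = make_crowded_variant(base_excl, base_kern,
                                              crowding_level=0.063)

for e in (0.0, 0.9):
    cavity = make_cavity(eccentricity=e, reference_radius=1.0, depth=0.2)
    rho = solve_gsd(cavity)
    profiles = {}
    for tag, excl, kern in (("base", base_excl, base_kern),
                            ("crowded", crowd_excl, crowd_kern)):
        wall = wall_potential(cavity, kern, template=rho)
        total = total_potential(exclusion_potential(rho, excl), wall)
        profiles[tag] = contour_profile(boltzmann_distribution(total),
                                        cavity, mode="elliptical")
    shift = edge_shift(profiles["base"], profiles["crowded"])
    print(f"e = {e:.1f}: inward edge shift with crowders = {shift*1e3:.0f} nm")

print("\nCrowders accumulating at the cavity wall extend the depletion "
      "zone; squeezing\nthe same effect into the narrow waist of the "
      "anisotropic cavity amplifies it.")
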