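"""Parameter recovery: fitting the plasmid model to sampled positions.

Draws plasmid positions from a Boltzmann distribution with known
parameters, histograms them at the 50 nm observational resolution, and
fits (a, wall_strength, r_b) by maximizing cosine similarity — the same
procedure applied to tracked microscopy data.
"""

import numpy as np

from cavity_demix import (
    ExclusionParams,
    KernelParams,
    Trajectory,
    bin_to_resolution,
    exclusion_potential,
    fit_plasmid_model,
    make_cavity,
    position_histogram,
    sample_boltzmann_positions,
    solve_gsd,
    total_potential,
    wall_potential,
)

cavity = make_cavity(eccentricity=0.6, reference_radius=1.0, depth=0.2)
rho = solve_gsd(cavity)
true_kernel = KernelParams(wall_strength=300.0, decay_range=0.05)
true_a = 1.1e-6

wall = wall_potential(cavity, true_kernel, template=rho)
total = total_potential(exclusion_potential(rho, ExclusionParams(true_a)), wall)
positions = sample_boltzmann_positions(total, 30_000, seed=1, cavity=cavity)

observed = bin_to_resolution(
    position_histogram(Trajectory(positions, 1.0), cavity, template=rho), 0.05)
fit = fit_plasmid_model(observed, cavity, rho, seed=0)

print(f"true:   a = {true_a:.2e}, wall_strength = {true_kernel.wall_strength}, "
      f"r_b = {true_kernel.decay_range}")
print(f"fitted: a = {fit.exclusion.a_coefficient:.2e}, "
      f"wall_strength = {fit.kernel.wall_strength:.1f}, "
      f"r_b = {fit.kernel.decay_range:.4f}")
print(f"cosine similarity of best fit: {fit.objective:.4f}")
print("\nr_b is sharply identified; a and wall_strength trade off weakly "
      "along the\nobjective's plateau, as expected for a Boltzmann model "
      "fit to a bounded domain.")
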