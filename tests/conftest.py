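"""Shared fixtures: cavities, solved density fields and model potentials.

Session scope keeps the mean-field solves (the slowest shared step) to one
per geometry for the whole run.
"""

import numpy as np
import pytest

import cavity_demix as cd


@pytest.fixture(scope="session")
def circle():
    return cd.make_cavity(0.0, 1.0)


@pytest.fixture(scope="session")
def cavity_e06():
    return cd.make_cavity(0.6, 1.0)


@pytest.fixture(scope="session")
def cavity_e09():
    return cd.make_cavity(0.9, 1.0)


#: reference "fitted-scale" plasmid model parameters used across tests:
#: exclusion coefficient at the reported magnitude, wall kernel chosen so
#: the boundary potential reaches 2 kBT ~190 nm from the wall
TRUE_A = 1.1e-6
TRUE_KERNEL = dict(family="exponential", wall_strength=300.0, decay_range=0.05)


@pytest.fixture(scope="session")
def density_e06(cavity_e06):
    return cd.solve_gsd(cavity_e06, grid_spacing=0.025)


@pytest.fixture(scope="session")
def density_e09(cavity_e09):
    return cd.solve_gsd(cavity_e09, grid_spacing=0.025)


def model_potential(cavity, density, a=TRUE_A, **kernel_kwargs):
    """Total plasmid potential U_chain + U_wall at reference parameters."""
    kern = cd.KernelParams(**{**TRUE_KERNEL, **kernel_kwargs})
    wall = cd.wall_potential(cavity, kern, template=density)
    return cd.total_potential(
        cd.exclusion_potential(density, cd.ExclusionParams(a)), wall)


@pytest.fixture(scope="session")
def potential_e06(cavity_e06, density_e06):
    return model_potential(cavity_e06, density_e06)


@pytest.fixture(scope="session")
def potential_e09(cavity_e09, density_e09):
    return model_potential(cavity_e09, density_e09)


@pytest.fixture(scope="session")
def plasmid_landscape_e09(potential_e09):
    """Free-energy landscape from the fitted-scale e=0.9 Boltzmann map,
    binned to the 50 nm observational resolution."""
    p50 = cd.bin_to_resolution(cd.boltzmann_distribution(potential_e09), 0.05)
    return cd.landscape_from_probability(p50)
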