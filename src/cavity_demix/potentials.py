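"""The plasmid's potential landscape inside the cavity.

Two repulsive contributions act on a small plasmid sharing a cavity with a
large chain:

* exclusion from regions of high chain concentration, linear in the local
  density: U_chain(r) = a * rho(r), with a in kBT um^3 bp^-1;
* a phenomenological wall repulsion obtained by integrating a short-range
  kernel u(d) over the cavity boundary,
  U_wall(r) = sum_s u(|r_s - r|) * ds.

The kernel is either exponential, u(d) = wall_strength * exp(-d / r_b), or a
truncated-shifted Lennard-Jones (WCA) form.  The equilibrium position
distribution is Boltzmann: P(r) ~ exp(-U_p(r)/kBT) with
U_p = U_chain + U_wall.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

from .errors import ConfigurationError, DataError, DomainError
from .fields import ScalarField
from .geometry import CavityGeometry, boundary_arrays
from .meanfield import DEFAULT_GRID_SPACING
from . import fields as _fields

__all__ = [
    "KernelParams",
    "ExclusionParams",
    "kernel_value",
    "wall_potential",
    "wall_potential_at",
    "WallIntegrator",
    "exclusion_potential",
    "total_potential",
    "boltzmann_distribution",
    "bin_to_resolution",
    "range_at_threshold",
    "effective_plasmid_radius",
]

# cap on the WCA kernel per unit arc length to keep d -> 0 finite;
# only affects cells the particle never occupies
_WCA_CAP = 1e3


@dataclass(frozen=True)
class KernelParams:
    """Wall-kernel parameters (per unit arc length of boundary).

    family "exponential": u(d) = wall_strength * exp(-d / decay_range),
    wall_strength in kBT um^-1, decay_range (r_b) in um.

    family "wca": truncated-shifted LJ, u(d) = 4 eps [(sigma/d)^12 -
    (sigma/d)^6] + eps for d < 2^(1/6) sigma, else 0; eps in kBT um^-1,
    sigma in um; capped at 1e3 kBT um^-1 as d -> 0.
    """

    family: str = "exponential"
    wall_strength: float = 300.0
    decay_range: float = 0.05
    epsilon: float = 1.0
    sigma: float = 0.2

    def __post_init__(self) -> None:
        if self.family not in ("exponential", "wca"):
            raise ConfigurationError(f"unknown kernel family {self.family!r}")
        if self.family == "exponential" and (self.wall_strength <= 0 or self.decay_range <= 0):
            raise ConfigurationError("wall_strength and decay_range must be positive")
        if self.family == "wca" and (self.epsilon <= 0 or self.sigma <= 0):
            raise ConfigurationError("epsilon and sigma must be positive")


@dataclass(frozen=True)
class ExclusionParams:
    """Chain-plasmid exclusion coefficient a, kBT um^3 bp^-1."""

    a_coefficient: float = 1.1e-6

    def __post_init__(self) -> None:
        if self.a_coefficient < 0:
            raise ConfigurationError("a_coefficient must be >= 0")


def kernel_value(params: KernelParams, distance) -> np.ndarray | float:
    """Kernel u(d) per unit arc length, kBT um^-1. Broadcasts over arrays."""
    d = np.asarray(distance, dtype=float)
    if np.any(d < 0):
        raise DomainError("distance must be >= 0")
    if params.family == "exponential":
        out = params.wall_strength * np.exp(-d / params.decay_range)
    else:
        cutoff = 2.0 ** (1.0 / 6.0) * params.sigma
        with np.errstate(divide="ignore", over="ignore"):
            sr6 = (params.sigma / np.where(d > 0, d, np.inf)) ** 6
            u = 4.0 * params.epsilon * (sr6**2 - sr6) + params.epsilon
        out = np.where(d < cutoff, u, 0.0)
        out = np.where(d == 0, _WCA_CAP, np.minimum(out, _WCA_CAP))
    if out.ndim == 0:
        return float(out)
    return out


def wall_potential_at(cavity: CavityGeometry, params: KernelParams, points,
                      n_segments: int = 720) -> np.ndarray:
    """Boundary-integrated wall potential at arbitrary points, kBT.

    Direct sum over the discretized boundary; distances are taken to the
    segment midpoints, which is below grid resolution for >= 720 segments.
    """
    if n_segments < 180:
        raise ConfigurationError("n_segments must be >= 180")
    xy, ds, _ = boundary_arrays(cavity, n_segments)
    p = np.atleast_2d(np.asarray(points, dtype=float))
    # (npoints, nseg) distance matrix
    d = np.sqrt(((p[:, None, :] - xy[None, :, :]) ** 2).sum(axis=-1))
    u = kernel_value(params, d)
    return u @ ds


class WallIntegrator:
    """Caches cell-to-boundary distances for repeated kernel evaluations.

    Fitting sweeps many kernel parameter sets over a fixed grid and cavity;
    the (interior cells x segments) distance matrix depends only on the
    geometry, so it is computed once.
    """

    def __init__(self, template: ScalarField, cavity: CavityGeometry,
                 n_segments: int = 720):
        if n_segments < 180:
            raise ConfigurationError("n_segments must be >= 180")
        self.template = template
        self.cavity = cavity
        xy, ds, _ = boundary_arrays(cavity, n_segments)
        X, Y = template.cell_centers()
        pts = np.column_stack([X[template.mask], Y[template.mask]])
        self._distances = np.sqrt(
            ((pts[:, None, :] - xy[None, :, :]) ** 2).sum(axis=-1)
        )
        self._ds = ds

    def potential(self, params: KernelParams) -> ScalarField:
        """U_wall on the cached grid for the given kernel, kBT."""
        u = kernel_value(params, self._distances) @ self._ds
        vals = np.zeros(self.template.shape)
        vals[self.template.mask] = u
        return self.template.copy_with(vals, role="potential")


def wall_potential(cavity: CavityGeometry, params: KernelParams,
                   grid_spacing: float = DEFAULT_GRID_SPACING,
                   n_segments: int = 720,
                   template: ScalarField | None = None) -> ScalarField:
    """U_wall(r) on a masked grid, kBT; increases toward the boundary."""
    if template is None:
        template = _fields.make_grid(cavity, grid_spacing)
    return WallIntegrator(template, cavity, n_segments).potential(params)


def exclusion_potential(density: ScalarField, params: ExclusionParams) -> ScalarField:
    """U_chain = a * rho, kBT; zero where the concentration vanishes."""
    if density.role != "concentration":
        raise DataError("exclusion_potential expects a concentration field")
    if np.any(density.values[density.mask] < 0):
        raise DataError("negative concentration values")
    return density.copy_with(params.a_coefficient * density.values, role="potential")


def total_potential(exclusion: ScalarField, wall: ScalarField) -> ScalarField:
    """Pointwise sum U_p = U_chain + U_wall on a shared grid."""
    if (exclusion.shape != wall.shape
            or exclusion.grid_spacing != wall.grid_spacing
            or not np.array_equal(exclusion.mask, wall.mask)):
        raise DataError("exclusion and wall fields are on different grids")
    return exclusion.copy_with(exclusion.values + wall.values, role="potential")


def boltzmann_distribution(potential: ScalarField) -> ScalarField:
    """P(r) ~ exp(-U_p / kBT), normalized to unit mass over the interior."""
    u = potential.values[potential.mask]
    if not np.any(np.isfinite(u)):
        raise DataError("potential is infinite everywhere inside the cavity")
    # subtract the minimum before exponentiating for numerical safety;
    # the Boltzmann weight is invariant to additive constants
    w = np.exp(-(u - u.min()))
    vals = np.zeros(potential.shape)
    vals[potential.mask] = w
    out = potential.copy_with(vals, role="probability")
    return out.normalized()


def bin_to_resolution(field: ScalarField, target_spacing: float = 0.05) -> ScalarField:
    """Block-sum a probability field down to a coarser resolution.

    Matches model maps to the ~50 nm pixel scale of tracked data.  The
    target spacing must be an integer multiple of the field spacing; mass is
    conserved and the result renormalized.
    """
    if field.role != "probability":
        raise DataError("bin_to_resolution expects a probability field")
    ratio = target_spacing / field.grid_spacing
    factor = int(round(ratio))
    if abs(ratio - factor) > 1e-9 or factor < 1:
        raise ConfigurationError(
            f"target spacing {target_spacing} is not an integer multiple of "
            f"the field spacing {field.grid_spacing}"
        )
    if factor == 1:
        return field.copy_with(field.values.copy())
    ny, nx = field.shape
    ny_c, nx_c = ny // factor, nx // factor
    ny_t, nx_t = ny_c * factor, nx_c * factor
    # probability mass per fine cell, block-summed
    mass = field.values[:ny_t, :nx_t] * field.mask[:ny_t, :nx_t] * field.grid_spacing**2
    coarse_mass = mass.reshape(ny_c, factor, nx_c, factor).sum(axis=(1, 3))
    coarse_mask = field.mask[:ny_t, :nx_t].reshape(ny_c, factor, nx_c, factor).any(axis=(1, 3))
    spacing = field.grid_spacing * factor
    vals = coarse_mass / spacing**2
    vals[~coarse_mask] = 0.0
    out = ScalarField(
        values=vals, mask=coarse_mask, grid_spacing=spacing,
        origin=(field.origin[0] + (factor - 1) / 2 * field.grid_spacing,
                field.origin[1] + (factor - 1) / 2 * field.grid_spacing),
        role="probability",
    )
    return out.normalized()


def range_at_threshold(cavity: CavityGeometry, params: KernelParams,
                       threshold: float = 2.0, n_segments: int = 720) -> float:
    """Distance from the wall at which U_wall decays to ``threshold`` kBT.

    Measured inward along the minor axis (the direction is a convention) by
    bisection on the continuous boundary sum.  Raises if the threshold is
    never reached between the wall-adjacent point and the centre.
    """
    if threshold <= 0:
        raise ConfigurationError("threshold must be positive")
    B = cavity.semi_minor

    def f(depth_in: float) -> float:
        pt = np.array([[0.0, B - depth_in]])
        return float(wall_potential_at(cavity, params, pt, n_segments)[0]) - threshold

    lo, hi = 1e-4 * B, B  # just inside the wall .. the centre
    if f(lo) < 0:
        raise DataError(
            f"wall potential near the boundary is already below {threshold} kBT"
        )
    if f(hi) > 0:
        raise DataError(
            f"wall potential never falls below {threshold} kBT along the minor axis"
        )
    return float(brentq(f, lo, hi, xtol=1e-6))


def effective_plasmid_radius(params: ExclusionParams,
                             basepairs_per_kuhn: int = 300) -> float:
    """Effective hard-sphere radius implied by the exclusion coefficient, um.

    Under the Flory picture the repulsion per Kuhn monomer is v * kBT * rho
    with v the mutual excluded volume; identifying v = a * basepairs_per_kuhn
    and approximating the plasmid as a sphere, v = (4/3) pi r_p^3.  Note this
    literal sphere identification gives r_p ~ 43 nm for a = 1.1e-6
    kBT um^3 bp^-1, smaller than light-scattering coil sizes; treat it as an
    order-of-magnitude estimate only.
    """
    v = params.a_coefficient * basepairs_per_kuhn  # um^3
    return float((3.0 * v / (4.0 * np.pi)) ** (1.0 / 3.0))
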