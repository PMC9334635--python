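"""Fitting the plasmid-potential parameters to an observed position map.

The free parameters — the exclusion coefficient a and the wall kernel
(wall_strength, r_b) for the exponential family, or (epsilon, sigma) for
WCA — are chosen to maximize the cosine similarity between the observed
binned plasmid position distribution and the model's Boltzmann map, binned
to the same resolution.  The search is derivative-free: a log-spaced seed
grid over the bounds followed by Nelder-Mead restarts from the best seeds.
"""

from __future__ import annotations

from dataclasses import dataclass, field as _dc_field

import numpy as np
from scipy.optimize import minimize

from .errors import ConfigurationError, DataError
from .fields import ScalarField
from .geometry import CavityGeometry
from .potentials import (
    ExclusionParams,
    KernelParams,
    WallIntegrator,
    bin_to_resolution,
    boltzmann_distribution,
    exclusion_potential,
    total_potential,
)

__all__ = ["FitResult", "cosine_similarity", "fit_plasmid_model", "model_distribution"]

#: default parameter bounds (log-searched)
DEFAULT_BOUNDS = {
    "a": (1e-8, 1e-4),          # kBT um^3 bp^-1
    "wall_strength": (1e-2, 1e3),  # kBT um^-1
    "decay_range": (0.02, 1.0),    # um
    "epsilon": (1e-2, 1e3),
    "sigma": (0.02, 1.0),
}


@dataclass
class FitResult:
    """Best-fit parameters with the optimizer trace."""

    exclusion: ExclusionParams
    kernel: KernelParams
    objective: float
    trace: list = _dc_field(default_factory=list)  # (param tuple, objective)
    config: dict = _dc_field(default_factory=dict)
    warning: str | None = None

    @property
    def params_dict(self) -> dict:
        d = {"a": self.exclusion.a_coefficient, "family": self.kernel.family}
        if self.kernel.family == "exponential":
            d.update(wall_strength=self.kernel.wall_strength,
                     decay_range=self.kernel.decay_range)
        else:
            d.update(epsilon=self.kernel.epsilon, sigma=self.kernel.sigma)
        return d


def cosine_similarity(p: ScalarField, q: ScalarField) -> float:
    """Cosine similarity sum(p_i q_i) / (|p| |q|) over interior cells.

    In [0, 1] for non-negative fields; invariant to overall positive
    rescaling of either field.
    """
    if p.shape != q.shape or not np.array_equal(p.mask, q.mask):
        raise DataError("fields must share a grid and mask")
    a = p.values[p.mask]
    b = q.values[q.mask]
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        raise DataError("zero-norm field in cosine similarity")
    return float(a @ b / (na * nb))


def model_distribution(exclusion: ExclusionParams, kernel_field: ScalarField,
                       density: ScalarField, target_spacing: float) -> ScalarField:
    """Boltzmann map for given exclusion params and a precomputed wall field."""
    u_chain = exclusion_potential(density, exclusion)
    u_total = total_potential(u_chain, kernel_field)
    p = boltzmann_distribution(u_total)
    return bin_to_resolution(p, target_spacing)


def _make_kernel(family: str, theta: np.ndarray) -> KernelParams:
    if family == "exponential":
        return KernelParams(family="exponential", wall_strength=theta[1],
                            decay_range=theta[2])
    return KernelParams(family="wca", epsilon=theta[1], sigma=theta[2])


def fit_plasmid_model(
    observed: ScalarField,
    cavity: CavityGeometry,
    density: ScalarField,
    family: str = "exponential",
    bounds: dict | None = None,
    init: dict | None = None,
    n_seed_per_axis: int = 5,
    n_restarts: int = 3,
    n_segments: int = 720,
    seed: int = 0,
    maxiter: int = 400,
) -> FitResult:
    """Fit (a, wall params) by maximizing cosine similarity to ``observed``.

    Parameters
    ----------
    observed : ScalarField
        Normalized position histogram (typically 50 nm bins).
    density : ScalarField
        Chain concentration on a grid commensurate with (or equal to) the
        observed grid after binning.
    family : "exponential" | "wca"
    bounds : dict
        Per-parameter (lo, hi); defaults in :data:`DEFAULT_BOUNDS`.
    init : dict
        Optional starting point added to the seed list.
    seed : int
        Fixed seed recorded in the config; the search itself is
        deterministic (grid + Nelder-Mead), the seed keys the trace.

    Notes
    -----
    The objective is plateaued and partially degenerate (an additive
    constant in U leaves the Boltzmann map unchanged), hence the
    derivative-free strategy with multiple restarts.
    """
    if observed.role != "probability":
        raise DataError("observed field must be a probability map")
    if family not in ("exponential", "wca"):
        raise ConfigurationError(f"unknown kernel family {family!r}")
    b = dict(DEFAULT_BOUNDS)
    if bounds:
        b.update(bounds)
    if family == "exponential":
        keys = ("a", "wall_strength", "decay_range")
    else:
        keys = ("a", "epsilon", "sigma")
    lo = np.array([b[k][0] for k in keys])
    hi = np.array([b[k][1] for k in keys])
    if np.any(lo <= 0) or np.any(hi <= lo):
        raise ConfigurationError("bounds must be positive with hi > lo")
    if init is not None:
        theta0 = np.array([init[k] for k in keys])
        if np.any(theta0 < lo) or np.any(theta0 > hi):
            raise ConfigurationError("init violates bounds")

    integrator = WallIntegrator(density, cavity, n_segments)
    target_spacing = observed.grid_spacing
    trace: list = []
    log_lo, log_hi = np.log(lo), np.log(hi)

    def objective(log_theta: np.ndarray) -> float:
        # smooth quadratic penalty outside the (log) bounds keeps the
        # simplex informed; a hard clip would create gradient-free plateaus
        penalty = float((np.clip(log_theta - log_hi, 0, None) ** 2).sum()
                        + (np.clip(log_lo - log_theta, 0, None) ** 2).sum())
        theta = np.exp(np.clip(log_theta, log_lo, log_hi))
        kernel = _make_kernel(family, theta)
        wall = integrator.potential(kernel)
        model = model_distribution(ExclusionParams(theta[0]), wall,
                                   density, target_spacing)
        score = cosine_similarity(observed, model)
        trace.append((tuple(theta), score))
        return -score + 10.0 * penalty

    # log-spaced seed grid
    axes = [np.linspace(np.log(l), np.log(h), n_seed_per_axis) for l, h in zip(lo, hi)]
    grid = np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1).reshape(-1, 3)
    seed_scores = np.array([-objective(p) for p in grid])
    order = np.argsort(seed_scores)[::-1]
    starts = [grid[i] for i in order[:n_restarts]]
    if init is not None:
        starts.insert(0, np.log(theta0))

    best_theta = np.exp(grid[order[0]])
    best_score = seed_scores[order[0]]
    warning = None
    improved = False
    for start in starts:
        res = minimize(objective, start, method="Nelder-Mead",
                       options={"maxiter": maxiter, "xatol": 1e-5, "fatol": 1e-12})
        theta = np.exp(np.clip(res.x, log_lo, log_hi))
        score = -objective(np.log(theta))  # penalty-free score at the clipped point
        if score > best_score:
            best_theta, best_score = theta, score
            improved = True
    if not improved:
        warning = "optimizer did not improve over the seed grid"

    return FitResult(
        exclusion=ExclusionParams(best_theta[0]),
        kernel=_make_kernel(family, best_theta),
        objective=float(best_score),
        trace=trace,
        config={
            "family": family,
            "bounds": {k: b[k] for k in keys},
            "n_seed_per_axis": n_seed_per_axis,
            "n_restarts": n_restarts,
            "n_segments": n_segments,
            "seed": seed,
            "maxiter": maxiter,
        },
        warning=warning,
    )
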