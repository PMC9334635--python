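"""Overdamped Brownian dynamics on an empirical free-energy landscape.

A point particle diffusing in a potential F(r) (in kBT) obeys the
overdamped Langevin equation; with diffusivity D and the Einstein relation
the Euler-Maruyama update is

    dr = -D grad F dt + sqrt(2 D dt) eta,   eta ~ N(0, 1) per axis.

The landscape is typically derived from an observed or fitted position
distribution through F = -log P (Boltzmann inversion), so long runs of the
dynamics must reproduce P — the consistency check used throughout the test
suite.  Steps that would leave the cavity mask are rejected and the noise
resampled (rejection-reflection), which preserves detailed balance to
O(dt).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ConfigurationError, DataError, SimulationError
from .fields import ScalarField
from .geometry import CavityGeometry, contains

__all__ = ["BDConfig", "Trajectory", "landscape_from_probability", "simulate_bd"]


@dataclass(frozen=True)
class BDConfig:
    """Brownian-dynamics run settings.

    diffusivity in um^2 s^-1 (default 0.5, typical for a ~100 nm particle
    in aqueous buffer); time_step in s.  The short-time exponents studied
    downstream are insensitive to D at matched lag ranges.
    """

    diffusivity: float = 0.5
    time_step: float = 1e-4
    n_steps: int = 3000
    n_clips: int = 250
    seed: int = 0
    boundary_rule: str = "reflect"
    start_rule: str = "stationary_sample"

    def __post_init__(self) -> None:
        if self.diffusivity <= 0 or self.time_step <= 0:
            raise ConfigurationError("diffusivity and time_step must be positive")
        if self.n_clips < 1 or self.n_steps < 1:
            raise ConfigurationError("n_clips and n_steps must be >= 1")
        if self.boundary_rule != "reflect":
            raise ConfigurationError("only the 'reflect' boundary rule is supported")
        if self.start_rule not in ("stationary_sample", "center"):
            raise ConfigurationError("start_rule must be 'stationary_sample' or 'center'")

    @property
    def step_scale(self) -> float:
        """RMS per-axis thermal step, sqrt(2 D dt), um."""
        return float(np.sqrt(2.0 * self.diffusivity * self.time_step))


@dataclass
class Trajectory:
    """Uniformly sampled 2D positions of one molecule/channel."""

    positions: np.ndarray  # (n, 2), um
    frame_interval: float  # s
    label: str = ""

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        if self.positions.ndim != 2 or self.positions.shape[1] != 2:
            raise DataError("positions must be an (n, 2) array")
        if len(self.positions) < 2:
            raise DataError("a trajectory needs at least 2 frames")
        if self.frame_interval <= 0:
            raise DataError("frame_interval must be positive")

    @property
    def times(self) -> np.ndarray:
        return self.frame_interval * np.arange(len(self.positions))

    @property
    def x(self) -> np.ndarray:
        return self.positions[:, 0]

    @property
    def y(self) -> np.ndarray:
        return self.positions[:, 1]


def landscape_from_probability(prob: ScalarField, floor_fraction: float = 0.5) -> ScalarField:
    """Boltzmann inversion F = -log P, kBT, with a probability floor.

    Cells with P below ``floor_fraction`` times the smallest positive
    interior value (including never-visited cells) are clamped to the floor,
    keeping them strongly repulsive but finite.  The minimum of F is shifted
    to 0.
    """
    if not (0.0 < floor_fraction <= 1.0):
        raise ConfigurationError("floor_fraction must be in (0, 1]")
    p = prob.values[prob.mask]
    positive = p[p > 0]
    if positive.size == 0:
        raise DataError("probability field has no positive mass")
    floor = floor_fraction * positive.min()
    f = -np.log(np.maximum(p, floor))
    f -= f.min()
    vals = np.zeros(prob.shape)
    vals[prob.mask] = f
    return prob.copy_with(vals, role="free_energy")


def _gradient_fields(landscape: ScalarField) -> tuple[np.ndarray, np.ndarray]:
    """Central-difference gradient of F with exterior cells filled.

    Exterior cells take the maximum interior value so the finite-difference
    stencil never pulls the particle outward across the wall; the mask-edge
    behaviour is dominated by the rejection rule anyway.
    """
    filled = np.where(landscape.mask, landscape.values,
                      landscape.values[landscape.mask].max())
    gy, gx = np.gradient(filled, landscape.grid_spacing)
    return gx, gy


def simulate_bd(landscape: ScalarField, cavity: CavityGeometry,
                config: BDConfig, max_reject: int = 50) -> list[Trajectory]:
    """Run ``config.n_clips`` independent walkers on a free-energy landscape.

    All clips advance together (vectorized Euler-Maruyama); each clip's
    noise stream is an independent, deterministically spawned child of
    ``config.seed``, so results are bitwise reproducible and independent of
    n_clips batching.

    Returns one :class:`Trajectory` per clip, sampled at every time step.
    """
    if landscape.role not in ("free_energy", "potential"):
        raise DataError("simulate_bd expects a free-energy/potential field")
    if config.step_scale >= landscape.grid_spacing:
        raise ConfigurationError(
            f"thermal step {config.step_scale:.4g} um exceeds the grid "
            f"spacing {landscape.grid_spacing}; reduce time_step"
        )
    gx, gy = _gradient_fields(landscape)
    gx_field = landscape.copy_with(gx)
    gy_field = landscape.copy_with(gy)

    n = config.n_clips
    # one child stream per clip (base noise), one for starts, one for
    # rejection resampling — all spawned deterministically from the seed
    root = np.random.SeedSequence(config.seed)
    children = root.spawn(n + 2)
    start_rng = np.random.Generator(np.random.PCG64(children[n]))
    reject_rng = np.random.Generator(np.random.PCG64(children[n + 1]))
    noise = np.stack([
        np.random.Generator(np.random.PCG64(children[i]))
        .standard_normal((config.n_steps, 2))
        for i in range(n)
    ], axis=1)  # (n_steps, n, 2)

    if config.start_rule == "center":
        pos = np.zeros((n, 2))
    else:
        pos = _sample_stationary(landscape, cavity, n, start_rng)

    D, dt = config.diffusivity, config.time_step
    sigma = config.step_scale
    out = np.empty((config.n_steps, n, 2))
    for step in range(config.n_steps):
        drift = np.column_stack([
            gx_field.interpolate(pos), gy_field.interpolate(pos)
        ])
        mean = pos - D * drift * dt
        proposal = mean + sigma * noise[step]
        bad = ~contains(cavity, proposal)
        tries = 0
        while np.any(bad):
            tries += 1
            if tries > max_reject:
                # keep the offenders in place for this step
                proposal[bad] = pos[bad]
                break
            k = int(bad.sum())
            proposal[bad] = mean[bad] + sigma * reject_rng.standard_normal((k, 2))
            bad = ~contains(cavity, proposal)
        pos = proposal
        if np.any(~contains(cavity, pos)):
            raise SimulationError("particle escaped the cavity after reflection")
        out[step] = pos

    return [
        Trajectory(positions=out[:, i, :], frame_interval=dt, label=f"clip{i}")
        for i in range(n)
    ]


def _sample_stationary(landscape: ScalarField, cavity: CavityGeometry, n: int,
                       rng: np.random.Generator) -> np.ndarray:
    """Draw start positions from exp(-F) over interior cells (cell centres,
    jittered uniformly within the cell; jittered points that land outside
    the cavity snap back to the cell centre)."""
    f = landscape.values[landscape.mask]
    w = np.exp(-(f - f.min()))
    w /= w.sum()
    X, Y = landscape.cell_centers()
    centers = np.column_stack([X[landscape.mask], Y[landscape.mask]])
    idx = rng.choice(len(centers), size=n, p=w)
    jitter = (rng.random((n, 2)) - 0.5) * landscape.grid_spacing
    pts = centers[idx] + jitter
    bad = ~contains(cavity, pts)
    pts[bad] = centers[idx][bad]
    return pts
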