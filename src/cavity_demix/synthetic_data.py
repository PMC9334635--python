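"""Synthetic inputs standing in for the microscope.

Three generators cover everything the analysis consumes:

* two coupled overdamped Langevin "blobs" in a cavity — a point-particle
  surrogate for two mutually excluding confined chains (Gaussian-core pair
  repulsion plus the boundary-integrated wall repulsion);
* i.i.d. plasmid positions drawn from a known Boltzmann distribution
  (rejection sampling), the ground truth for parameter-recovery tests;
* noisy two-channel movies rendered from trajectories with a Gaussian
  point-spread function, for exercising the tracking stage.

Crowding is emulated at the parameter level: added inert crowders compress
the chain and deplete the wall zone, which the model maps to a scaled
exclusion coefficient and wall decay range.
"""

from __future__ import annotations

from dataclasses import dataclass, field as _dc_field

import numpy as np
from scipy.special import erf

from .errors import ConfigurationError, DataError, DomainError
from .fields import ScalarField
from .geometry import CavityGeometry, contains, make_cavity
from .landscape_dynamics import Trajectory, _gradient_fields
from .potentials import ExclusionParams, KernelParams, wall_potential

__all__ = [
    "TwoBlobConfig",
    "RenderConfig",
    "simulate_two_blobs",
    "simulate_two_blob_ensemble",
    "sample_boltzmann_positions",
    "make_crowded_variant",
    "render_movie",
    "dextran_radius",
]


@dataclass(frozen=True)
class TwoBlobConfig:
    """Conditions for the two-blob surrogate of two confined chains.

    Defaults emulate two lambda-DNA-sized coils (Rg ~ 0.7 um) in the
    r0 = 1 um equal-area cavity family: a soft Gaussian-core repulsion of
    range comparable to the coil size, a chain-scale wall softness, and a
    centre-of-mass diffusivity giving pole-swap dwell times of order 10 s
    at high eccentricity.
    """

    cavity: CavityGeometry = _dc_field(default_factory=lambda: make_cavity(0.0, 1.0))
    pair_strength: float = 7.0  # kBT (coil-overlap free energy scale)
    pair_range: float = 0.7  # um (Gaussian-core sigma ~ coil gyration radius)
    wall_kernel: KernelParams = _dc_field(
        default_factory=lambda: KernelParams(family="exponential",
                                             wall_strength=20.0, decay_range=0.08))
    diffusivity: float = 0.4  # um^2 s^-1 (confined-coil centre-of-mass scale)
    time_step: float = 2.5e-3  # s
    n_frames: int = 2400
    frame_interval: float = 0.05  # s
    seed: int = 0
    wall_grid_spacing: float = 0.05  # um, for the precomputed wall force field

    def __post_init__(self) -> None:
        if self.pair_range <= 0:
            raise ConfigurationError("pair_range must be positive")
        ratio = self.frame_interval / self.time_step
        if abs(ratio - round(ratio)) > 1e-9 or round(ratio) < 1:
            raise ConfigurationError(
                "frame_interval must be an integer multiple of time_step")
        step = np.sqrt(2.0 * self.diffusivity * self.time_step)
        if step >= self.wall_grid_spacing:
            raise ConfigurationError(
                f"thermal step {step:.4g} um exceeds the wall-field grid "
                f"spacing {self.wall_grid_spacing}; reduce time_step")

    @property
    def steps_per_frame(self) -> int:
        return int(round(self.frame_interval / self.time_step))


@dataclass(frozen=True)
class RenderConfig:
    """Synthetic two-colour imaging conditions.

    Default photon budget (5000/frame, Poisson) keeps the centroid noise
    well below the 50 nm analysis bin.
    """

    pixel_size: float = 0.05  # um
    image_shape: tuple[int, int] = (64, 64)  # (ny, nx)
    psf_sigma: float = 0.15  # um
    photons_per_frame: float = 5000.0
    background_level: float = 10.0  # counts / pixel
    noise_model: str = "poisson"  # poisson | gaussian | none
    seed: int = 0

    def __post_init__(self) -> None:
        if self.psf_sigma < self.pixel_size / 2:
            raise ConfigurationError("psf_sigma must be >= pixel_size / 2")
        if self.photons_per_frame <= 0:
            raise ConfigurationError("photons_per_frame must be positive")
        if self.noise_model not in ("poisson", "gaussian", "none"):
            raise ConfigurationError("noise_model must be poisson|gaussian|none")

    @property
    def origin(self) -> tuple[float, float]:
        ny, nx = self.image_shape
        return (-(nx - 1) / 2 * self.pixel_size, -(ny - 1) / 2 * self.pixel_size)


# ---------------------------------------------------------------------------
# two-blob Langevin surrogate
# ---------------------------------------------------------------------------

def simulate_two_blob_ensemble(config: TwoBlobConfig, n_replicas: int = 1
                               ) -> list[tuple[Trajectory, Trajectory]]:
    """Simulate independent two-blob systems, vectorized across replicas.

    Euler-Maruyama with the pairwise Gaussian-core force evaluated
    analytically and the wall force interpolated from a precomputed
    boundary-integral potential field.  Steps leaving the cavity are
    rejected with resampled noise.  Deterministic under (seed, config);
    replica k of an n-replica run equals replica k of any other run with
    the same seed (per-replica spawned noise streams).
    """
    if n_replicas < 1:
        raise ConfigurationError("n_replicas must be >= 1")
    cavity = config.cavity
    wall = wall_potential(cavity, config.wall_kernel,
                          grid_spacing=config.wall_grid_spacing)
    gx, gy = _gradient_fields(wall)
    gx_field = wall.copy_with(gx)
    gy_field = wall.copy_with(gy)

    n_steps = config.n_frames * config.steps_per_frame
    D, dt = config.diffusivity, config.time_step
    sigma = np.sqrt(2.0 * D * dt)
    A2, s2 = config.pair_strength, config.pair_range**2

    root = np.random.SeedSequence(config.seed)
    children = root.spawn(n_replicas + 1)
    reject_rng = np.random.Generator(np.random.PCG64(children[n_replicas]))
    rngs = [np.random.Generator(np.random.PCG64(c)) for c in children[:n_replicas]]

    # start the blobs apart along the major axis, mirrored, half-way out
    x0 = 0.5 * cavity.semi_major
    pos = np.empty((n_replicas, 2, 2))
    pos[:, 0] = [+x0, 0.0]
    pos[:, 1] = [-x0, 0.0]

    frames = np.empty((config.n_frames, n_replicas, 2, 2))
    spf = config.steps_per_frame
    chunk = 20_000  # noise pre-generation block (keeps memory bounded)
    for chunk_start in range(0, n_steps, chunk):
        m = min(chunk, n_steps - chunk_start)
        noise_block = np.stack(
            [r.standard_normal((m, 2, 2)) for r in rngs], axis=1
        )  # (m, n_replicas, 2, 2)
        for j in range(m):
            step = chunk_start + j
            r12 = pos[:, 0] - pos[:, 1]
            # Gaussian-core pair force on blob 0 (blob 1 gets the negative)
            f_pair = (A2 / s2) * np.exp(
                -(r12**2).sum(axis=1, keepdims=True) / (2 * s2)) * r12
            flat = pos.reshape(-1, 2)
            fw = -np.column_stack([gx_field.interpolate(flat),
                                   gy_field.interpolate(flat)])
            force = fw.reshape(n_replicas, 2, 2)
            force[:, 0] += f_pair
            force[:, 1] -= f_pair
            mean = pos + D * force * dt
            proposal = mean + sigma * noise_block[j]
            bad = ~contains(cavity, proposal)
            tries = 0
            while np.any(bad):
                tries += 1
                if tries > 50:
                    proposal[bad] = pos[bad]
                    break
                k = int(bad.sum())
                proposal[bad] = mean[bad] + sigma * reject_rng.standard_normal((k, 2))
                bad = ~contains(cavity, proposal)
            pos = proposal
            if (step + 1) % spf == 0:
                frames[(step + 1) // spf - 1] = pos

    out = []
    for i in range(n_replicas):
        out.append((
            Trajectory(frames[:, i, 0, :], config.frame_interval, label=f"rep{i}-ch0"),
            Trajectory(frames[:, i, 1, :], config.frame_interval, label=f"rep{i}-ch1"),
        ))
    return out


def simulate_two_blobs(config: TwoBlobConfig) -> tuple[Trajectory, Trajectory]:
    """Single two-blob realization; see :func:`simulate_two_blob_ensemble`."""
    return simulate_two_blob_ensemble(config, n_replicas=1)[0]


# ---------------------------------------------------------------------------
# Boltzmann position sampling
# ---------------------------------------------------------------------------

def sample_boltzmann_positions(potential: ScalarField, n: int, seed: int = 0,
                               batch: int = 65536,
                               cavity: CavityGeometry | None = None) -> np.ndarray:
    """Draw n i.i.d. positions from P ~ exp(-U) by rejection sampling.

    Proposals are uniform over the grid bounding box; a proposal at a
    masked-in cell is accepted with probability exp(-(U_cell - U_min)),
    proposals on exterior cells are rejected.  This samples exactly the
    piecewise-constant (cell-binned) Boltzmann density.  Pass ``cavity``
    to additionally reject the slivers of boundary cells outside the exact
    ellipse (guaranteeing every sample lies inside the cavity).
    Deterministic under ``seed``.
    """
    if n < 1:
        raise ConfigurationError("n must be >= 1")
    u = potential.values
    mask = potential.mask
    umin = u[mask].min()
    weight = np.where(mask, np.exp(-(u - umin)), 0.0)
    rng = np.random.Generator(np.random.PCG64(seed))
    ny, nx = potential.shape
    dx = potential.grid_spacing
    x_lo = potential.origin[0] - dx / 2
    y_lo = potential.origin[1] - dx / 2
    out = np.empty((0, 2))
    proposed = accepted = 0
    while len(out) < n:
        p = np.column_stack([
            x_lo + rng.random(batch) * nx * dx,
            y_lo + rng.random(batch) * ny * dx,
        ])
        ix = np.clip(((p[:, 0] - x_lo) / dx).astype(int), 0, nx - 1)
        iy = np.clip(((p[:, 1] - y_lo) / dx).astype(int), 0, ny - 1)
        accept = rng.random(batch) < weight[iy, ix]
        if cavity is not None:
            accept &= contains(cavity, p)
        out = np.vstack([out, p[accept]])
        proposed += batch
        accepted += int(accept.sum())
        if proposed >= 10 * batch and accepted / proposed < 1e-4:
            raise DataError(
                "rejection acceptance rate below 1e-4; use a tighter envelope "
                "or a less extreme potential")
    return out[:n]


# ---------------------------------------------------------------------------
# crowding emulation
# ---------------------------------------------------------------------------

def make_crowded_variant(exclusion: ExclusionParams, kernel: KernelParams,
                         crowding_level: float, c1: float = 5.0, c2: float = 5.0
                         ) -> tuple[ExclusionParams, KernelParams]:
    """Parameter-level emulation of macromolecular crowding.

    Crowders accumulate at the cavity perimeter (extending the effective
    wall depletion zone) and compact the chain (raising the effective
    exclusion): the wall decay range scales by (1 + c1 * v_phi) and the
    exclusion coefficient by (1 + c2 * v_phi), with v_phi the crowder
    volume fraction.  c1, c2 are phenomenological.
    """
    if not (0.0 <= crowding_level < 0.5):
        raise DomainError("crowding_level must be in [0, 0.5)")
    if kernel.family != "exponential":
        raise ConfigurationError("crowding emulation is defined for the "
                                 "exponential kernel")
    new_kernel = KernelParams(
        family="exponential",
        wall_strength=kernel.wall_strength,
        decay_range=kernel.decay_range * (1.0 + c1 * crowding_level),
    )
    new_exclusion = ExclusionParams(
        a_coefficient=exclusion.a_coefficient * (1.0 + c2 * crowding_level))
    return new_exclusion, new_kernel


# ---------------------------------------------------------------------------
# movie rendering
# ---------------------------------------------------------------------------

def render_movie(trajs: dict[str, Trajectory], config: RenderConfig
                 ) -> tuple[dict[str, np.ndarray], dict[str, np.ndarray]]:
    """Render per-channel image stacks from trajectories.

    Each frame holds an integrated-Gaussian blob (total intensity
    ``photons_per_frame``) at the particle position plus a uniform
    background, with Poisson or Gaussian shot noise (or none).

    Returns (stacks, clipped): per-channel (n_frames, ny, nx) float arrays
    and per-channel boolean flags marking frames whose blob centre lies
    within 3 psf sigma of the frame edge (clipped mass).
    """
    ny, nx = config.image_shape
    px = config.pixel_size
    ox, oy = config.origin
    x_edges = ox - px / 2 + px * np.arange(nx + 1)
    y_edges = oy - px / 2 + px * np.arange(ny + 1)
    root = np.random.SeedSequence(config.seed)
    rngs = {k: np.random.Generator(np.random.PCG64(c))
            for k, c in zip(trajs, root.spawn(len(trajs)))}

    stacks: dict[str, np.ndarray] = {}
    clipped: dict[str, np.ndarray] = {}
    s = config.psf_sigma * np.sqrt(2.0)
    for label, traj in trajs.items():
        n_frames = len(traj.positions)
        stack = np.empty((n_frames, ny, nx))
        flags = np.zeros(n_frames, dtype=bool)
        for i, (x0, y0) in enumerate(traj.positions):
            cx = 0.5 * (erf((x_edges[1:] - x0) / s) - erf((x_edges[:-1] - x0) / s))
            cy = 0.5 * (erf((y_edges[1:] - y0) / s) - erf((y_edges[:-1] - y0) / s))
            signal = config.photons_per_frame * np.outer(cy, cx)
            frame = signal + config.background_level
            if config.noise_model == "poisson":
                frame = rngs[label].poisson(frame).astype(float)
            elif config.noise_model == "gaussian":
                frame = frame + rngs[label].normal(0.0, np.sqrt(np.maximum(frame, 1.0)))
            stack[i] = frame
            margin = 3.0 * config.psf_sigma
            if (x0 < x_edges[0] + margin or x0 > x_edges[-1] - margin
                    or y0 < y_edges[0] + margin or y0 > y_edges[-1] - margin):
                flags[i] = True
        stacks[label] = stack
        clipped[label] = flags
    return stacks, clipped


def dextran_radius(molecular_weight: float) -> float:
    """Gyration radius of dextran from its molar mass, nm.

    Empirical scaling R_g = 0.066 * M_w^0.43 with M_w in g/mol; 5 kDa
    dextran gives ~2.6 nm.
    """
    if molecular_weight <= 0:
        raise DomainError("molecular_weight must be positive")
    return float(0.066 * molecular_weight**0.43)
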