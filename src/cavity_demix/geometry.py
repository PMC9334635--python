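"""Elliptical cavity geometry.

The experimental cavities form a constant-area family: as eccentricity e is
raised at fixed etch depth h, the semi-axes change so that the in-plane area
(and hence, at fixed depth, the volume) is preserved.  With reference radius
r0 (the radius of the e = 0 circle),

    A = r0 * (1 - e^2)^(-1/4)     (semi-major, along +x)
    B = r0 * (1 - e^2)^(+1/4)     (semi-minor, along +y)

so that A * B = r0^2 for every member of the family.  All modules share the
cavity-centred Cartesian frame with x along the major axis and lengths in
micrometres.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import quad

from .errors import ConfigurationError, DomainError

__all__ = [
    "CavityGeometry",
    "BoundarySegment",
    "make_cavity",
    "contains",
    "boundary_segments",
    "effective_radius",
    "ellipse_perimeter",
]

_REL_TOL = 1e-12


@dataclass(frozen=True)
class CavityGeometry:
    """An elliptical cavity, centred at the origin, major axis along +x.

    Attributes
    ----------
    eccentricity : float
        e in [0, 1).
    semi_major, semi_minor : float
        Semi-axes A >= B > 0, micrometres.
    depth : float
        Etch depth h, micrometres (default 0.2 um).
    """

    eccentricity: float
    semi_major: float
    semi_minor: float
    depth: float = 0.2
    center: tuple[float, float] = (0.0, 0.0)
    major_axis_direction: tuple[float, float] = (1.0, 0.0)

    def __post_init__(self) -> None:
        if not (0.0 <= self.eccentricity < 1.0):
            raise DomainError(f"eccentricity must be in [0, 1), got {self.eccentricity}")
        if not (self.semi_major >= self.semi_minor > 0.0):
            raise DomainError("require semi_major >= semi_minor > 0")
        if self.depth <= 0.0:
            raise DomainError("depth must be positive")
        expected_minor = self.semi_major * np.sqrt(1.0 - self.eccentricity**2)
        if abs(expected_minor - self.semi_minor) > _REL_TOL * max(1.0, self.semi_minor):
            raise DomainError(
                "semi_minor inconsistent with eccentricity: "
                f"expected {expected_minor}, got {self.semi_minor}"
            )

    @property
    def area(self) -> float:
        """In-plane area pi*A*B, um^2."""
        return float(np.pi * self.semi_major * self.semi_minor)

    @property
    def reference_radius(self) -> float:
        """Radius r0 of the equal-area circle, um."""
        return float(np.sqrt(self.semi_major * self.semi_minor))


@dataclass(frozen=True)
class BoundarySegment:
    """A discretized patch of the cavity boundary."""

    midpoint: tuple[float, float]  # um
    arc_length: float  # ds, um
    parameter_angle: float  # t, radians

    # arrays are friendlier downstream; kept as a struct for the contract


def make_cavity(eccentricity: float, reference_radius: float, depth: float = 0.2) -> CavityGeometry:
    """Build the equal-area ellipse for a given eccentricity.

    Parameters
    ----------
    eccentricity : float in [0, 1)
    reference_radius : float
        r0, the radius of the e = 0 circle of the family, um.
    depth : float
        Etch depth h, um.
    """
    if not (0.0 <= eccentricity < 1.0):
        raise DomainError(f"eccentricity must be in [0, 1), got {eccentricity}")
    if reference_radius <= 0.0:
        raise DomainError("reference_radius must be positive")
    if depth <= 0.0:
        raise DomainError("depth must be positive")
    one_minus_e2 = 1.0 - eccentricity**2
    semi_major = reference_radius * one_minus_e2 ** (-0.25)
    semi_minor = reference_radius * one_minus_e2 ** (+0.25)
    return CavityGeometry(
        eccentricity=eccentricity,
        semi_major=semi_major,
        semi_minor=semi_minor,
        depth=depth,
    )


def contains(cavity: CavityGeometry, point) -> np.ndarray | bool:
    """Interior test (boundary inclusive): (x/A)^2 + (y/B)^2 <= 1.

    Accepts a single (x, y) pair or an (..., 2) array; broadcasts.
    """
    p = np.asarray(point, dtype=float)
    x, y = p[..., 0], p[..., 1]
    val = (x / cavity.semi_major) ** 2 + (y / cavity.semi_minor) ** 2
    out = val <= 1.0
    if out.ndim == 0:
        return bool(out)
    return out


def effective_radius(cavity: CavityGeometry, point) -> np.ndarray | float:
    """Effective radial coordinate r_eff = sqrt((x/A)^2 + (y/B)^2).

    0 at the centre, 1 on the cavity wall; labels confocal elliptical
    contours. Broadcasts over (..., 2) arrays.
    """
    p = np.asarray(point, dtype=float)
    x, y = p[..., 0], p[..., 1]
    out = np.sqrt((x / cavity.semi_major) ** 2 + (y / cavity.semi_minor) ** 2)
    if out.ndim == 0:
        return float(out)
    return out


def boundary_segments(cavity: CavityGeometry, n_segments: int) -> list[BoundarySegment]:
    """Discretize the boundary into patches uniform in the parameter angle t.

    Midpoints are (A cos t, B sin t) at the segment-centre angles; the
    arc-length weight ds = sqrt(A^2 sin^2 t + B^2 cos^2 t) * dt carries the
    ellipse metric.
    """
    xy, ds, t_mid = boundary_arrays(cavity, n_segments)
    return [
        BoundarySegment(
            midpoint=(float(p[0]), float(p[1])),
            arc_length=float(w),
            parameter_angle=float(t),
        )
        for p, w, t in zip(xy, ds, t_mid)
    ]


def boundary_arrays(cavity: CavityGeometry, n_segments: int):
    """Vectorized boundary discretization used by the potential integrators.

    Returns (midpoints (n, 2), arc_lengths (n,), centre angles (n,)).
    """
    if n_segments < 8:
        raise ConfigurationError(f"n_segments must be >= 8, got {n_segments}")
    A, B = cavity.semi_major, cavity.semi_minor
    dt = 2.0 * np.pi / n_segments
    t_mid = (np.arange(n_segments) + 0.5) * dt
    xy = np.column_stack([A * np.cos(t_mid), B * np.sin(t_mid)])
    ds = np.sqrt(A**2 * np.sin(t_mid) ** 2 + B**2 * np.cos(t_mid) ** 2) * dt
    return xy, ds, t_mid


def ellipse_perimeter(cavity: CavityGeometry) -> float:
    """Perimeter by adaptive quadrature of the arc-length integrand."""
    A, B = cavity.semi_major, cavity.semi_minor

    def integrand(t: float) -> float:
        return np.sqrt(A**2 * np.sin(t) ** 2 + B**2 * np.cos(t) ** 2)

    val, _ = quad(integrand, 0.0, 2.0 * np.pi, limit=200)
    return float(val)
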