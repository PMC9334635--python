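"""Scalar fields on a regular grid masked to the cavity interior.

A :class:`ScalarField` holds values at cell centres of a regular Cartesian
grid together with a boolean interior mask derived from the cavity geometry.
The same container carries every field in the pipeline — chain concentration
(bp um^-3), potentials and free energies (kBT) and probability densities
(um^-2) — distinguished by its ``role`` tag.  Exterior cells are flagged by
the mask and are never silently folded into integrals.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field as _dc_field, replace

import h5py
import numpy as np

from .errors import ConfigurationError, DataError, DomainError
from .geometry import CavityGeometry, contains

__all__ = ["ScalarField", "make_grid", "save_field", "load_field"]


@dataclass
class ScalarField:
    """Values on a regular 2D grid, masked to a cavity interior.

    Attributes
    ----------
    values : (ny, nx) float array
        Cell-centre values; exterior cells hold 0 but are masked out.
    mask : (ny, nx) bool array
        True on interior cells.
    grid_spacing : float
        Cell edge, um (square cells).
    origin : (float, float)
        Coordinates of the lower-left cell centre (x0, y0), um.
    role : str
        One of "concentration", "potential", "free_energy", "probability",
        or "generic".
    """

    values: np.ndarray
    mask: np.ndarray
    grid_spacing: float
    origin: tuple[float, float]
    role: str = "generic"
    meta: dict = _dc_field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.values.shape != self.mask.shape:
            raise DataError("values and mask shapes differ")
        if self.grid_spacing <= 0:
            raise ConfigurationError("grid_spacing must be positive")
        if not np.all(np.isfinite(self.values[self.mask])):
            raise DataError("non-finite values on interior cells")

    # -- coordinates -------------------------------------------------

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def x_centers(self) -> np.ndarray:
        return self.origin[0] + self.grid_spacing * np.arange(self.shape[1])

    @property
    def y_centers(self) -> np.ndarray:
        return self.origin[1] + self.grid_spacing * np.arange(self.shape[0])

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """Meshgrid (X, Y) of cell-centre coordinates, each (ny, nx)."""
        return np.meshgrid(self.x_centers, self.y_centers)

    # -- algebra over the mask ---------------------------------------

    def integrate(self) -> float:
        """Sum over interior cells times the cell area."""
        return float(self.values[self.mask].sum() * self.grid_spacing**2)

    def copy_with(self, values: np.ndarray, role: str | None = None) -> "ScalarField":
        return replace(self, values=np.asarray(values, dtype=float),
                       role=self.role if role is None else role)

    def normalized(self) -> "ScalarField":
        """Rescale interior values so the field integrates to 1 (probability)."""
        total = self.integrate()
        if total <= 0:
            raise DataError("cannot normalize a field with non-positive mass")
        vals = np.where(self.mask, self.values / total, 0.0)
        return self.copy_with(vals, role="probability")

    def interpolate(self, points, fill_value: float = 0.0) -> np.ndarray:
        """Bilinear interpolation at (..., 2) points.

        Exterior grid values participate as stored (0 for Dirichlet fields);
        points outside the grid bounding box raise.
        """
        p = np.atleast_2d(np.asarray(points, dtype=float))
        x = (p[..., 0] - self.origin[0]) / self.grid_spacing
        y = (p[..., 1] - self.origin[1]) / self.grid_spacing
        ny, nx = self.shape
        if np.any(x < -0.5) or np.any(x > nx - 0.5) or np.any(y < -0.5) or np.any(y > ny - 0.5):
            raise DomainError("interpolation point outside the grid bounding box")
        x0 = np.clip(np.floor(x).astype(int), 0, nx - 2)
        y0 = np.clip(np.floor(y).astype(int), 0, ny - 2)
        fx = np.clip(x - x0, 0.0, 1.0)
        fy = np.clip(y - y0, 0.0, 1.0)
        v = self.values
        out = (
            v[y0, x0] * (1 - fx) * (1 - fy)
            + v[y0, x0 + 1] * fx * (1 - fy)
            + v[y0 + 1, x0] * (1 - fx) * fy
            + v[y0 + 1, x0 + 1] * fx * fy
        )
        return out


def make_grid(cavity: CavityGeometry, grid_spacing: float,
              padding_cells: int = 1) -> ScalarField:
    """Build an all-zero field whose mask covers the cavity interior.

    The grid is symmetric about the origin so that the ellipse's mirror
    symmetries are exactly representable; ``padding_cells`` rings of exterior
    cells surround the ellipse bounding box.
    """
    if grid_spacing <= 0:
        raise ConfigurationError("grid_spacing must be positive")
    A, B = cavity.semi_major, cavity.semi_minor
    # symmetric cell-centre layout: centres at +-(k + 1/2) * dx
    nx_half = int(np.ceil(A / grid_spacing + padding_cells))
    ny_half = int(np.ceil(B / grid_spacing + padding_cells))
    nx, ny = 2 * nx_half, 2 * ny_half
    origin = (-(nx_half - 0.5) * grid_spacing, -(ny_half - 0.5) * grid_spacing)
    xs = origin[0] + grid_spacing * np.arange(nx)
    ys = origin[1] + grid_spacing * np.arange(ny)
    X, Y = np.meshgrid(xs, ys)
    pts = np.stack([X, Y], axis=-1)
    mask = contains(cavity, pts)
    return ScalarField(values=np.zeros((ny, nx)), mask=mask,
                       grid_spacing=grid_spacing, origin=origin)


def save_field(field: ScalarField, path, metadata: dict | None = None) -> None:
    """Write a field to an HDF5 container (datasets: values, mask, origin, spacing).

    Solver metadata goes into a JSON string attribute.
    """
    with h5py.File(path, "w") as f:
        f.create_dataset("values", data=field.values)
        f.create_dataset("mask", data=field.mask.astype(np.uint8))
        f.create_dataset("origin", data=np.asarray(field.origin))
        f.create_dataset("spacing", data=field.grid_spacing)
        f.attrs["role"] = field.role
        f.attrs["metadata"] = json.dumps(metadata or {})


def load_field(path) -> tuple[ScalarField, dict]:
    with h5py.File(path, "r") as f:
        field = ScalarField(
            values=f["values"][...],
            mask=f["mask"][...].astype(bool),
            grid_spacing=float(f["spacing"][()]),
            origin=tuple(np.asarray(f["origin"][...], dtype=float)),
            role=str(f.attrs.get("role", "generic")),
        )
        metadata = json.loads(f.attrs.get("metadata", "{}"))
    return field, metadata
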