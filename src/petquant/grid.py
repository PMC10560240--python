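"""Voxel grids and activity-concentration volumes.

Coordinate convention: right-handed scanner coordinates in mm, axes ordered
(x, y, z) = (radial-at-centre, tangential, axial).  Voxel values are activity
concentrations in Bq/mL.  Arrays are stored C-contiguous with the axial index
slowest, i.e. ``values[iz, iy, ix]``; all user-facing vectors (voxel size,
origin, shape centres) are in (x, y, z) order.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

VALID_NUCLIDES = ("F18", "Ga68", "none")


def _as_vec3(v, dtype=float) -> np.ndarray:
    a = np.asarray(v, dtype=dtype)
    if a.shape != (3,):
        raise ValueError(f"expected a 3-vector, got shape {a.shape}")
    return a


@dataclass(frozen=True)
class GridSpec:
    """A regular voxel grid in scanner space.

    Parameters
    ----------
    voxel_size:
        (x, y, z) voxel spacing in mm; strictly positive.
    dims:
        (nx, ny, nz) voxel counts, each >= 1.
    origin:
        mm position of the *centre* of voxel (0, 0, 0).
    """

    voxel_size: np.ndarray
    dims: np.ndarray
    origin: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "voxel_size", _as_vec3(self.voxel_size))
        object.__setattr__(self, "dims", _as_vec3(self.dims, dtype=int))
        object.__setattr__(self, "origin", _as_vec3(self.origin))
        if not np.all(self.voxel_size > 0):
            raise ValueError("voxel_size must be strictly positive")
        if not np.all(self.dims >= 1):
            raise ValueError("dims must be >= 1 on each axis")

    @classmethod
    def centred(cls, extent_mm: Sequence[float], voxel_size: Sequence[float]) -> "GridSpec":
        """Grid symmetric about the scanner isocentre covering ``extent_mm``."""
        vs = _as_vec3(voxel_size)
        extent = _as_vec3(extent_mm)
        dims = np.maximum(np.ceil(extent / vs).astype(int), 1)
        origin = -(dims - 1) / 2.0 * vs
        return cls(voxel_size=vs, dims=dims, origin=origin)

    @property
    def shape(self) -> tuple[int, int, int]:
        """Array storage shape (nz, ny, nx)."""
        nx, ny, nz = self.dims
        return (int(nz), int(ny), int(nx))

    @property
    def voxel_volume_ml(self) -> float:
        return float(np.prod(self.voxel_size)) / 1000.0

    def coords(self, axis: int) -> np.ndarray:
        """Voxel-centre positions (mm) along spatial axis 0=x, 1=y, 2=z."""
        n = int(self.dims[axis])
        return self.origin[axis] + np.arange(n) * self.voxel_size[axis]

    @property
    def bounds(self) -> tuple[np.ndarray, np.ndarray]:
        """Outer edges of the grid: (low, high) in mm, (x, y, z) order."""
        lo = self.origin - self.voxel_size / 2.0
        hi = self.origin + (self.dims - 0.5) * self.voxel_size
        return lo, hi

    def index_of(self, xyz: Sequence[float]) -> tuple[int, int, int]:
        """Nearest voxel index (iz, iy, ix) for a point in mm."""
        p = _as_vec3(xyz)
        idx = np.rint((p - self.origin) / self.voxel_size).astype(int)
        idx = np.clip(idx, 0, self.dims - 1)
        return int(idx[2]), int(idx[1]), int(idx[0])

    def position_of(self, index: Sequence[int]) -> np.ndarray:
        """mm position (x, y, z) of the centre of voxel ``(iz, iy, ix)``."""
        iz, iy, ix = index
        return self.origin + np.array([ix, iy, iz]) * self.voxel_size


@dataclass
class ActivityVolume:
    """A 3D activity-concentration field on a :class:`GridSpec`.

    ``values`` has shape ``grid.shape`` = (nz, ny, nx) in Bq/mL.
    ``time_offset_min`` is minutes elapsed since activity calibration.
    """

    values: np.ndarray
    grid: GridSpec
    radionuclide: str = "none"
    time_offset_min: float = 0.0
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != self.grid.shape:
            raise ValueError(
                f"values shape {self.values.shape} does not match grid shape {self.grid.shape}"
            )
        if self.radionuclide not in VALID_NUCLIDES:
            raise ValueError(f"unknown radionuclide {self.radionuclide!r}")
        if not np.isfinite(self.values.sum()):
            raise ValueError("total activity is not finite")

    @property
    def total_activity_bq(self) -> float:
        """Sum of voxel concentrations times voxel volume (Bq)."""
        return float(self.values.sum()) * self.grid.voxel_volume_ml

    def with_values(self, values: np.ndarray) -> "ActivityVolume":
        return ActivityVolume(
            values=values,
            grid=self.grid,
            radionuclide=self.radionuclide,
            time_offset_min=self.time_offset_min,
            meta=dict(self.meta),
        )

    def copy(self) -> "ActivityVolume":
        return self.with_values(self.values.copy())
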