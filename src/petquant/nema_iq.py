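"""NEMA NU 4-2008 image-quality analysis.

Uniformity, spill-over ratios and rod recovery coefficients, with the
root-sum-of-squares error propagation for the rod RC:

    RC_rod = max pixel of the rod / mean of the uniform region
    SD_RC  = RC * sqrt((SD_lp / Mean_lp)^2 + (SD_bg / Mean_bg)^2)

where the line-profile statistics come from a 10 mm axial profile through
the rod's maximum pixel.  All VOI statistics use the population SD and a
voxel belongs to a VOI iff its centre is inside the shape.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .grid import ActivityVolume, GridSpec
from . import phantoms as ph


@dataclass(frozen=True)
class VOISpec:
    """Cylindrical (axial) or spherical volume of interest."""

    shape: str                      # "cylinder" | "sphere"
    centre: tuple[float, float, float]
    radius: float
    height: Optional[float] = None  # cylinders only

    def __post_init__(self):
        if self.shape not in ("cylinder", "sphere"):
            raise ValueError(f"unknown VOI shape {self.shape!r}")
        if self.radius <= 0:
            raise ValueError("VOI radius must be > 0")
        if self.shape == "cylinder" and (self.height is None or self.height <= 0):
            raise ValueError("cylindrical VOI needs height > 0")
        object.__setattr__(self, "centre", tuple(float(c) for c in self.centre))

    def mask(self, grid: GridSpec) -> np.ndarray:
        """Boolean membership mask (voxel-centre rule), validated in-grid."""
        lo, hi = grid.bounds
        half = np.full(3, self.radius)
        if self.shape == "cylinder":
            half[2] = self.height / 2.0
        c = np.asarray(self.centre)
        if np.any(c - half < lo - 1e-9) or np.any(c + half > hi + 1e-9):
            raise ValueError(f"VOI at {self.centre} (radius {self.radius:g}) extends "
                             "outside the image grid")
        xs = grid.coords(0) - self.centre[0]
        ys = grid.coords(1) - self.centre[1]
        zs = grid.coords(2) - self.centre[2]
        trans = (xs[None, :] ** 2 + ys[:, None] ** 2)  # (ny, nx)
        if self.shape == "cylinder":
            m = (trans <= self.radius**2)[None, :, :] & \
                (np.abs(zs) <= self.height / 2.0)[:, None, None]
        else:
            m = trans[None, :, :] + (zs**2)[:, None, None] <= self.radius**2
        return m

    def translated(self, offset: Sequence[float]) -> "VOISpec":
        off = np.asarray(offset, dtype=float)
        return VOISpec(shape=self.shape, centre=tuple(np.asarray(self.centre) + off),
                       radius=self.radius, height=self.height)


@dataclass(frozen=True)
class UniformityResult:
    mean: float
    minimum: float
    maximum: float
    sd: float
    pct_sd: float
    n_voxels: int


@dataclass(frozen=True)
class SORResult:
    sor_air: float
    sor_water: float
    mean_air: float
    mean_water: float


@dataclass(frozen=True)
class RodRCResult:
    diameter_mm: float
    rc: float
    sd_rc: float
    max_pixel: float
    lineprofile_mean: float
    lineprofile_sd: float


def voi_statistics(vol: ActivityVolume, voi: VOISpec) -> UniformityResult:
    """Population statistics over VOI member voxels (no minimum-size guard)."""
    vals = vol.values[voi.mask(vol.grid)]
    if vals.size == 0:
        raise ValueError("VOI contains no voxels")
    mean = float(vals.mean())
    sd = float(vals.std())  # population (n) convention
    return UniformityResult(mean=mean, minimum=float(vals.min()), maximum=float(vals.max()),
                            sd=sd, pct_sd=100.0 * sd / mean if mean != 0 else 0.0,
                            n_voxels=int(vals.size))


def uniformity_metrics(vol: ActivityVolume, voi: VOISpec,
                       min_voxels: int = 100) -> UniformityResult:
    """NEMA uniformity over the standard cylindrical VOI (>= ``min_voxels``)."""
    res = voi_statistics(vol, voi)
    if res.n_voxels < min_voxels:
        raise ValueError(f"uniformity VOI has only {res.n_voxels} voxels "
                         f"(need >= {min_voxels})")
    return res


def spillover(vol: ActivityVolume, air_voi: VOISpec, water_voi: VOISpec,
              background: UniformityResult) -> SORResult:
    """Spill-over ratios: cold-insert VOI means over the uniform-region mean."""
    if background.mean <= 0:
        raise ValueError("background mean must be > 0")
    mean_air = voi_statistics(vol, air_voi).mean
    mean_water = voi_statistics(vol, water_voi).mean
    return SORResult(sor_air=mean_air / background.mean,
                     sor_water=mean_water / background.mean,
                     mean_air=mean_air, mean_water=mean_water)


def reformat_axial(vol: ActivityVolume, thickness_mm: float, centre_mm: float
                   ) -> ActivityVolume:
    """Voxelwise mean over an axial slab, returned as a single-slice volume."""
    zs = vol.grid.coords(2)
    sel = np.abs(zs - centre_mm) <= thickness_mm / 2.0 + 1e-9
    if not sel.any():
        raise ValueError("slab does not overlap the volume axially")
    slab = vol.values[sel].mean(axis=0)[None, :, :]
    grid = GridSpec(
        voxel_size=(vol.grid.voxel_size[0], vol.grid.voxel_size[1], thickness_mm),
        dims=(int(vol.grid.dims[0]), int(vol.grid.dims[1]), 1),
        origin=(vol.grid.origin[0], vol.grid.origin[1], centre_mm),
    )
    return ActivityVolume(values=slab, grid=grid, radionuclide=vol.radionuclide,
                          time_offset_min=vol.time_offset_min, meta=dict(vol.meta))


def propagate_rc_sd(rc: float, lp_sd: float, lp_mean: float,
                    bg_sd: float, bg_mean: float) -> float:
    """Root-sum-of-squares propagation of the two relative SDs onto the RC."""
    return rc * math.sqrt((lp_sd / lp_mean) ** 2 + (bg_sd / bg_mean) ** 2)


def rod_recovery(vol: ActivityVolume, rods: Sequence[tuple[float, tuple[float, float]]],
                 background: UniformityResult, slab_centre_mm: float,
                 slab_thickness_mm: float = 10.0, profile_length_mm: float = 10.0
                 ) -> list[RodRCResult]:
    """Rod recovery coefficients on a reformatted 10 mm slab.

    ``rods`` is a list of (diameter_mm, (x, y)) rod positions.  For each rod
    the maximum pixel is searched in a circular ROI of twice the rod
    diameter; the RC error is propagated from an axial line profile through
    the maximum and from the background statistics.
    """
    if background.mean <= 0:
        raise ValueError("background mean must be > 0")
    slab = reformat_axial(vol, slab_thickness_mm, slab_centre_mm)
    plane = slab.values[0]
    grid = vol.grid
    xs, ys = grid.coords(0), grid.coords(1)

    # pairwise ROI overlap check (ROI radius = rod diameter)
    for i in range(len(rods)):
        for j in range(i + 1, len(rods)):
            di, (xi, yi) = rods[i]
            dj, (xj, yj) = rods[j]
            if math.hypot(xi - xj, yi - yj) < di + dj:
                warnings.warn(f"ROIs of the {di:g} mm and {dj:g} mm rods overlap",
                              stacklevel=2)

    zs = vol.grid.coords(2)
    prof_sel = np.abs(zs - slab_centre_mm) <= profile_length_mm / 2.0 + 1e-9
    results = []
    for diameter, (cx, cy) in rods:
        roi_radius = diameter  # ROI diameter is twice the rod diameter
        roi = (xs[None, :] - cx) ** 2 + (ys[:, None] - cy) ** 2 <= roi_radius**2
        if not roi.any():
            raise ValueError(f"ROI of the {diameter:g} mm rod contains no voxels")
        masked = np.where(roi, plane, -np.inf)
        iy, ix = np.unravel_index(int(np.argmax(masked)), plane.shape)
        max_pixel = float(plane[iy, ix])
        r_max = math.hypot(xs[ix] - cx, ys[iy] - cy)
        if r_max > roi_radius - float(grid.voxel_size[0]):
            warnings.warn(f"{diameter:g} mm rod: maximum at the ROI boundary, "
                          "possible mislocalization", stacklevel=2)
        rc = max_pixel / background.mean
        profile = vol.values[prof_sel, iy, ix]
        lp_mean = float(profile.mean())
        lp_sd = float(profile.std())
        sd_rc = propagate_rc_sd(rc, lp_sd, lp_mean, background.sd, background.mean)
        results.append(RodRCResult(diameter_mm=diameter, rc=rc, sd_rc=sd_rc,
                                   max_pixel=max_pixel, lineprofile_mean=lp_mean,
                                   lineprofile_sd=lp_sd))
    return results


# ---------------------------------------------------------------------------
# standard VOI layout for the IQ phantom (derived from the simulator geometry)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class IQLayout:
    uniformity_voi: VOISpec
    air_voi: VOISpec
    water_voi: VOISpec
    rods: tuple[tuple[float, tuple[float, float]], ...]
    rod_slab_centre_mm: float


def iq_layout(offset_mm: Sequence[float] = (0.0, 0.0)) -> IQLayout:
    """Analysis VOIs of the NEMA NU 4 IQ phantom, optionally off-centred.

    Uniformity: 22 mm diameter x 10 mm cylinder in the structure-free part;
    spill-over: 4 mm diameter x 7.5 mm cylinders inside the cold inserts.
    """
    ox, oy = (float(v) for v in offset_mm)
    h = ph.IQ_CHAMBER_HEIGHT
    z_ins = h / 2.0 - ph.IQ_INSERT_HEIGHT / 2.0
    z_plug = -h / 2.0 + ph.IQ_ROD_SECTION_LENGTH / 2.0
    uniform = VOISpec(shape="cylinder", centre=(ox, oy, 3.0), radius=11.0, height=10.0)
    air = VOISpec(shape="cylinder", centre=(ph.IQ_INSERT_OFFSET + ox, oy, z_ins),
                  radius=2.0, height=7.5)
    water = VOISpec(shape="cylinder", centre=(-ph.IQ_INSERT_OFFSET + ox, oy, z_ins),
                    radius=2.0, height=7.5)
    rods = tuple((d, (x + ox, y + oy)) for d, (x, y) in ph.iq_rod_centres())
    return IQLayout(uniformity_voi=uniform, air_voi=air, water_voi=water,
                    rods=rods, rod_slab_centre_mm=z_plug)
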