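"""NEMA NU 4-2008 spatial-resolution measurement.

Orthogonal profiles are drawn through the maximum pixel of a line-source
image; the profile maximum is refined by a parabolic fit through the highest
sample and its two neighbours, and FWHM / FWTM are obtained by linear
interpolation between the samples straddling the half / tenth threshold on
each side of the peak.  Line sources are in air, so no background is
subtracted.  For off-centred sources the radial direction points from the
FOV centre through the source and profiles are resampled bilinearly.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.ndimage import map_coordinates

from .grid import ActivityVolume

DIRECTIONS = ("radial", "tangential", "axial")


@dataclass(frozen=True)
class Profile:
    """A 1D intensity profile along one direction (positions in mm)."""

    positions: np.ndarray
    values: np.ndarray
    axis_label: str = ""

    def __post_init__(self):
        object.__setattr__(self, "positions", np.asarray(self.positions, dtype=float))
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))
        if self.positions.ndim != 1 or self.positions.shape != self.values.shape:
            raise ValueError("positions and values must be matching 1D arrays")
        if self.positions.size < 5:
            raise ValueError("profile needs at least 5 samples")
        d = np.diff(self.positions)
        if np.any(d <= 0) or not np.allclose(d, d[0], rtol=1e-6, atol=1e-9):
            raise ValueError("positions must be strictly increasing and uniformly spaced")


@dataclass(frozen=True)
class ResolutionResult:
    """FWHM / FWTM per direction plus the peak location and fitted apex."""

    fwhm: dict[str, float]        # mm per direction
    fwtm: dict[str, float]
    peak_mm: tuple[float, float, float]
    apex: float                   # parabola-fitted profile maximum

    def __post_init__(self):
        for d in self.fwhm:
            if not (self.fwtm[d] >= self.fwhm[d] > 0):
                raise ValueError(f"require fwtm >= fwhm > 0 in direction {d}")


def locate_peak(vol: ActivityVolume, search_mask: Optional[np.ndarray] = None
                ) -> tuple[int, int, int]:
    """Index (iz, iy, ix) of the global maximum; ties -> smallest index."""
    values = vol.values
    if search_mask is not None:
        region = np.where(search_mask, values, -np.inf)
    else:
        region = values
    vmax = region.max()
    vmin = region[np.isfinite(region)].min()
    if vmax == vmin:
        raise ValueError("no peak: region is constant")
    flat = int(np.argmax(region))  # first occurrence = lexicographically smallest
    return tuple(int(i) for i in np.unravel_index(flat, values.shape))


def _parabolic_apex(v_left: float, v_peak: float, v_right: float) -> float:
    """Maximum of the parabola through three equally spaced samples."""
    denom = v_left - 2.0 * v_peak + v_right
    if denom >= 0:
        raise ValueError("samples do not form a peak (non-concave apex)")
    delta = 0.5 * (v_left - v_right) / denom
    return v_peak - 0.25 * (v_left - v_right) * delta


def width_at_fraction(profile: Profile, fraction: float) -> float:
    """Width (mm) of the profile at ``fraction`` of its parabola-fitted apex.

    Crossings are found by scanning outward from the highest sample and
    linearly interpolating between the first pair of samples straddling the
    threshold on each side.
    """
    if not (0.0 < fraction < 1.0):
        raise ValueError("fraction must be in (0, 1)")
    x, v = profile.positions, profile.values
    i = int(np.argmax(v))
    if i == 0 or i == v.size - 1:
        raise ValueError("profile peak lies on the boundary; cannot fit apex")
    apex = _parabolic_apex(v[i - 1], v[i], v[i + 1])
    thr = fraction * apex

    def crossing(step: int) -> float:
        j = i
        while 0 <= j + step < v.size:
            j += step
            if v[j] < thr:
                # interpolate between samples j-step (>= thr) and j (< thr)
                x0, x1 = x[j - step], x[j]
                v0, v1 = v[j - step], v[j]
                return x0 + (thr - v0) / (v1 - v0) * (x1 - x0)
        raise ValueError(
            f"profile truncated: never falls below {fraction:g} x apex on one side"
        )

    if v[i] < thr:
        raise ValueError("fraction threshold lies above the highest sample")
    return crossing(+1) - crossing(-1)


def _axis_profile(vol: ActivityVolume, peak: tuple[int, int, int], axis: int,
                  label: str) -> Profile:
    """Grid-axis-aligned profile through the peak voxel; axis 0=x, 1=y, 2=z."""
    iz, iy, ix = peak
    if axis == 0:
        vals = vol.values[iz, iy, :]
    elif axis == 1:
        vals = vol.values[iz, :, ix]
    else:
        vals = vol.values[:, iy, ix]
    return Profile(positions=vol.grid.coords(axis), values=vals, axis_label=label)


def _rotated_profile(vol: ActivityVolume, peak: tuple[int, int, int],
                     direction: np.ndarray, label: str) -> Profile:
    """Transaxial profile through the peak along an arbitrary unit vector,
    sampled bilinearly at the transaxial voxel pitch."""
    iz, iy, ix = peak
    grid = vol.grid
    spacing = float(grid.voxel_size[0])
    centre = grid.position_of(peak)
    plane = vol.values[iz]  # (ny, nx)
    lo, hi = grid.bounds
    # number of steps until the line leaves the grid on either side
    steps = []
    for sgn in (-1.0, 1.0):
        n = np.inf
        for k in range(2):
            d = sgn * direction[k] * spacing
            if d > 0:
                n = min(n, (hi[k] - spacing / 2 - centre[k]) / d)
            elif d < 0:
                n = min(n, (lo[k] + spacing / 2 - centre[k]) / -abs(d))
        steps.append(int(max(np.floor(n), 0)))
    s = np.arange(-steps[0], steps[1] + 1) * spacing
    pts_x = centre[0] + s * direction[0]
    pts_y = centre[1] + s * direction[1]
    # map mm -> fractional indices (row = y, col = x)
    rows = (pts_y - grid.origin[1]) / grid.voxel_size[1]
    cols = (pts_x - grid.origin[0]) / grid.voxel_size[0]
    vals = map_coordinates(plane, np.vstack([rows, cols]), order=1, mode="nearest")
    return Profile(positions=s, values=vals, axis_label=label)


def analyse_line_source(vol: ActivityVolume, centred_tolerance_mm: float = 1.0
                        ) -> ResolutionResult:
    """NEMA resolution analysis of a volume containing one axial line source.

    Radial/tangential follow the grid axes (x, y) for a centred source; for a
    source further than ``centred_tolerance_mm`` from the FOV axis the
    transaxial profiles are rotated so that radial points from the FOV centre
    through the source.
    """
    peak = locate_peak(vol)
    peak_mm = vol.grid.position_of(peak)
    r = float(np.hypot(peak_mm[0], peak_mm[1]))
    if r <= centred_tolerance_mm:
        profiles = {
            "radial": _axis_profile(vol, peak, 0, "radial"),
            "tangential": _axis_profile(vol, peak, 1, "tangential"),
        }
    else:
        u = np.array([peak_mm[0], peak_mm[1]]) / r
        t = np.array([-u[1], u[0]])
        profiles = {
            "radial": _rotated_profile(vol, peak, u, "radial"),
            "tangential": _rotated_profile(vol, peak, t, "tangential"),
        }
    profiles["axial"] = _axis_profile(vol, peak, 2, "axial")

    fwhm = {d: width_at_fraction(p, 0.5) for d, p in profiles.items()}
    fwtm = {d: width_at_fraction(p, 0.1) for d, p in profiles.items()}
    pr = profiles["radial"].values
    i = int(np.argmax(pr))
    apex = _parabolic_apex(pr[i - 1], pr[i], pr[i + 1])
    return ResolutionResult(fwhm=fwhm, fwtm=fwtm,
                            peak_mm=tuple(float(c) for c in peak_mm), apex=float(apex))
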