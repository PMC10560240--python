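"""Hot-sphere recovery coefficients via background-adapted 50% isocontours.

Following the EANM-style procedure: the maximum pixel A_max of each sphere is
taken inside an encompassing spherical VOI (twice the sphere diameter); the
A50 mean is computed over the 26-connected component of voxels at or above
the background-adapted threshold

    T = B + 0.5 * (A_max - B)

containing the maximum, where B is the mean of a uniform background region.
Recovery coefficients divide both by the true fill concentration.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.ndimage import binary_erosion, label

from .grid import ActivityVolume
from .nema_iq import VOISpec

_CONN26 = np.ones((3, 3, 3), dtype=bool)


@dataclass(frozen=True)
class SphereRCResult:
    diameter_mm: float
    a_max: float                 # Bq/mL
    a50: float                   # Bq/mL
    rc_max: float
    rc_a50: float
    mask_voxels: int
    truth_bq_ml: float

    def __post_init__(self):
        if self.a50 > self.a_max + 1e-9:
            raise ValueError("a50 cannot exceed a_max")
        if self.mask_voxels < 1:
            raise ValueError("isocontour mask must contain at least one voxel")


def iso50_mask(vol: ActivityVolume, search_voi: VOISpec,
               background_mean: float) -> np.ndarray:
    """Background-adapted 50% isocontour mask within a search VOI.

    Returns the 26-connected component (>= threshold, ties included) that
    contains the VOI maximum, clipped to the VOI.  Raises if the maximum does
    not rise above the background; warns if the component touches the VOI
    boundary (the object may be clipped).
    """
    voi_mask = search_voi.mask(vol.grid)
    masked = np.where(voi_mask, vol.values, -np.inf)
    flat = int(np.argmax(masked))
    peak = np.unravel_index(flat, vol.values.shape)
    vmax = float(vol.values[peak])
    # relative tie tolerance so a region numerically level with the
    # background (e.g. zero contrast) is reliably flagged undetectable
    if vmax <= background_mean * (1.0 + 1e-9):
        raise ValueError("sphere not detectable: maximum does not exceed the "
                         "background mean")
    threshold = background_mean + 0.5 * (vmax - background_mean)
    above = (vol.values >= threshold) & voi_mask
    labels, _ = label(above, structure=_CONN26)
    mask = labels == labels[peak]
    interior = binary_erosion(voi_mask, structure=_CONN26, border_value=0)
    if (mask & ~interior).any():
        warnings.warn("isocontour touches the search-VOI boundary", stacklevel=2)
    return mask


def sphere_rc(vol: ActivityVolume, diameter_mm: float,
              centre: Sequence[float], background_mean: float,
              truth_bq_ml: float, search_factor: float = 2.0) -> SphereRCResult:
    """Recovery coefficients of one hot sphere.

    The search VOI is a sphere of ``search_factor`` times the physical
    diameter centred on the known sphere position.
    """
    if truth_bq_ml <= 0:
        raise ValueError("truth concentration must be > 0")
    voi = VOISpec(shape="sphere", centre=tuple(float(c) for c in centre),
                  radius=search_factor * diameter_mm / 2.0)
    mask = iso50_mask(vol, voi, background_mean)
    a_max = float(vol.values[voi.mask(vol.grid)].max())
    a50 = float(vol.values[mask].mean())
    return SphereRCResult(diameter_mm=diameter_mm, a_max=a_max, a50=a50,
                          rc_max=a_max / truth_bq_ml, rc_a50=a50 / truth_bq_ml,
                          mask_voxels=int(mask.sum()), truth_bq_ml=truth_bq_ml)
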