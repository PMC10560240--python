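"""Validation study on the anatomical rat phantom.

Four rat phantoms, each with four spherical tumours (10/10/8/8 mm) filled at
0.3 / 0.6 / 1.2 / 2.4 MBq/mL with the concentration-to-position assignment
cyclically rotated per rat, are imaged at five time points 30 min apart so
that physical decay sweeps the tumour activities downward.  Measured A_max
and A50 per tumour are compared against the decay-corrected theoretical
concentration A_calc at each acquisition start via Pearson correlation and
Bland-Altman statistics (percent difference referenced to A_calc).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .grid import ActivityVolume
from .nema_iq import VOISpec, voi_statistics
from .nuclides import HALF_LIFE_MIN, decay_factor  # re-exported
from . import phantoms as ph
from .spheres import sphere_rc

QUADRANT_OFFSETS = ((50.0, 50.0), (-50.0, 50.0), (-50.0, -50.0), (50.0, -50.0))
LIVER_VOI_RADIUS = 5.0


@dataclass(frozen=True)
class TumourMeasurement:
    rat: int
    position: str                 # UL / UR / BL / BR
    diameter_mm: float
    timepoint: int
    a_calc: float                 # Bq/mL, decay-corrected truth at acquisition start
    a_max: Optional[float] = None
    a50: Optional[float] = None
    detectable: bool = True

    def __post_init__(self):
        if self.a_calc <= 0:
            raise ValueError("a_calc must be > 0")
        if self.diameter_mm not in (8.0, 10.0):
            raise ValueError("tumour diameter must be 8 or 10 mm")


@dataclass(frozen=True)
class AgreementStats:
    pearson_r: float
    r_squared: float
    bias: float                   # mean percent difference
    loa_low: float                # bias - 1.96 SD
    loa_high: float               # bias + 1.96 SD
    n: int


@dataclass
class RatSeries:
    """Phantom series plus the ground-truth table for one radionuclide.

    ``specs[t]`` is the four-rat scene at time point ``t`` (concentrations
    already decay-scaled to the acquisition start); ``truth`` has one row per
    rat x tumour x time point; ``liver_vois[rat]`` is the per-rat background
    VOI used for the A50 adaptation.
    """

    specs: list[ph.PhantomSpec]
    truth: pd.DataFrame
    liver_vois: dict[int, VOISpec]
    radionuclide: str
    interval_min: float


def build_rat_series(tumour_fill_mbq_ml: Sequence[float] = (0.3, 0.6, 1.2, 2.4),
                     n_timepoints: int = 5, interval_min: float = 30.0,
                     radionuclide: str = "F18", n_rats: int = 4,
                     offsets: Sequence[tuple[float, float]] = QUADRANT_OFFSETS
                     ) -> RatSeries:
    """Build the multi-rat phantom series and its decay-corrected truth table.

    Rat ``r`` assigns the fill concentrations to (UL, UR, BL, BR) rotated by
    ``r`` positions; the bladder is present in the first two rats only.  At
    time point ``t`` every concentration is scaled by the physical decay over
    ``t * interval_min`` minutes, and A_calc equals fill x decay.
    """
    if len(tumour_fill_mbq_ml) != 4:
        raise ValueError("need exactly four tumour fill concentrations")
    if n_rats > len(offsets):
        raise ValueError("not enough placement offsets for the requested rats")

    rows = []
    liver_vois: dict[int, VOISpec] = {}
    rat_specs_t0: list[ph.PhantomSpec] = []
    for r in range(n_rats):
        fills = tuple(np.roll(np.asarray(tumour_fill_mbq_ml, dtype=float), r))
        spec = ph.make_phantom("rat", tumour_mbq_ml=fills, include_bladder=(r < 2))
        off = np.array([offsets[r][0], offsets[r][1], 0.0])
        rat_specs_t0.append(spec.translated(off))
        liver_vois[r] = VOISpec(shape="sphere",
                                centre=tuple(np.asarray(ph.RAT_LIVER_CENTRE) + off),
                                radius=LIVER_VOI_RADIUS)
        for pos, fill in zip(ph.RAT_TUMOUR_POSITIONS, fills):
            centre = np.asarray(ph.RAT_TUMOUR_CENTRES[pos]) + off
            for t in range(n_timepoints):
                d = decay_factor(radionuclide, t * interval_min)
                rows.append(dict(rat=r, position=pos,
                                 diameter_mm=ph.RAT_TUMOUR_DIAMETERS[pos],
                                 timepoint=t, time_min=t * interval_min,
                                 fill_bq_ml=fill * 1e6, a_calc_bq_ml=fill * 1e6 * d,
                                 centre_x=centre[0], centre_y=centre[1],
                                 centre_z=centre[2]))

    specs = []
    for t in range(n_timepoints):
        d = decay_factor(radionuclide, t * interval_min)
        shapes = []
        for spec in rat_specs_t0:
            for s in spec.all_shapes():
                scaled = s
                if s.concentration_bq_ml > 0:
                    scaled = ph.replace(s, concentration_bq_ml=s.concentration_bq_ml * d,
                                        contained=False)
                else:
                    scaled = ph.replace(s, contained=False)
                shapes.append(scaled)
        specs.append(ph.PhantomSpec(name=f"rat_scene_t{t}", shapes=tuple(shapes),
                                    background=None))

    truth = pd.DataFrame(rows).sort_values(["timepoint", "rat", "position"],
                                           ignore_index=True)
    return RatSeries(specs=specs, truth=truth, liver_vois=liver_vois,
                     radionuclide=radionuclide, interval_min=interval_min)


def quantify_rat_volume(vol: ActivityVolume, truth_rows: pd.DataFrame,
                        liver_vois: dict[int, VOISpec]) -> list[TumourMeasurement]:
    """Measure A_max / A50 of every tumour of one acquisition.

    The per-rat background for the isocontour adaptation is the mean in the
    liver VOI.  Tumours whose maximum does not exceed that background are
    returned flagged (``detectable=False``) and carry no measurements.
    """
    out = []
    bg_by_rat = {r: voi_statistics(vol, voi).mean for r, voi in liver_vois.items()}
    for row in truth_rows.itertuples(index=False):
        bg = bg_by_rat[row.rat]
        try:
            res = sphere_rc(vol, diameter_mm=row.diameter_mm,
                            centre=(row.centre_x, row.centre_y, row.centre_z),
                            background_mean=bg, truth_bq_ml=row.a_calc_bq_ml)
        except ValueError:
            out.append(TumourMeasurement(rat=row.rat, position=row.position,
                                         diameter_mm=row.diameter_mm,
                                         timepoint=row.timepoint,
                                         a_calc=row.a_calc_bq_ml, detectable=False))
            continue
        out.append(TumourMeasurement(rat=row.rat, position=row.position,
                                     diameter_mm=row.diameter_mm,
                                     timepoint=row.timepoint, a_calc=row.a_calc_bq_ml,
                                     a_max=res.a_max, a50=res.a50))
    return out


def agreement(measurements: Sequence[TumourMeasurement], which: str = "a50"
              ) -> AgreementStats:
    """Pearson correlation and Bland-Altman agreement vs A_calc.

    Percent differences are referenced to the truth: d = 100 (m - A_calc) /
    A_calc; limits of agreement are bias +/- 1.96 sample SD.  Flagged
    (undetectable) rows are excluded.
    """
    if which not in ("a_max", "a50"):
        raise ValueError("which must be 'a_max' or 'a50'")
    rows = [m for m in measurements if m.detectable]
    if len(rows) < 3:
        raise ValueError(f"need at least 3 detectable measurements, got {len(rows)}")
    measured = np.array([getattr(m, which) for m in rows], dtype=float)
    truth = np.array([m.a_calc for m in rows], dtype=float)
    if np.ptp(measured) == 0 or np.ptp(truth) == 0:
        raise ValueError("zero variance: correlation undefined")
    r = float(stats.pearsonr(measured, truth).statistic)
    d = 100.0 * (measured - truth) / truth
    bias = float(d.mean())
    sd = float(d.std(ddof=1)) if d.size > 1 else 0.0
    return AgreementStats(pearson_r=r, r_squared=r * r, bias=bias,
                          loa_low=bias - 1.96 * sd, loa_high=bias + 1.96 * sd,
                          n=int(d.size))


def measurements_frame(measurements: Sequence[TumourMeasurement]) -> pd.DataFrame:
    """Tabular view of tumour measurements (one row per tumour)."""
    return pd.DataFrame([m.__dict__ for m in measurements])
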