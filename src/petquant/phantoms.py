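"""Declarative phantom models and their sub-voxel rasterization.

Every object imaged in the study is expressed as an ordered list of geometric
primitives (spheres, cylinders, boxes) with fill concentrations; later shapes
override earlier ones where they overlap, which lets cold inserts and drilled
rods be carved out of a hot chamber.  Rasterization averages ``supersample^3``
regularly spaced sub-points per voxel so that integrated activities converge
to the closed-form volumes of the primitives.

The module ships builders for the four phantoms of the study:

``nema_nu4_iq``
    NEMA NU 4-2008 image-quality phantom: 33.5 mm ID x 63 mm fillable chamber
    with a uniform section, two cold inserts (air / cold water, 8 mm ID x
    14 mm) and a solid PMMA section drilled with 5 hot rods (1-5 mm).
``mhs``
    Micro-hollow-sphere phantom: 40 mm ID x 82 mm cylinder with four hollow
    spheres of 7.86 / 6.23 / 4.95 / 3.95 mm inner diameter.
``line_source``
    A 1 mm ID capillary segment used for spatial-resolution measurements.
``rat``
    The 3D-printed anatomical rat phantom: plastic body with air lungs,
    liver / bladder / kidney cavities at the printed volumes and four
    spherical "tumours" (10 / 10 / 8 / 8 mm) near the body surface.
``scatter_cylinder``
    A 4 mm ID x 90 mm fillable scattering source used to mimic the presence
    of additional animals in the field of view.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Optional, Sequence

import numpy as np

from .grid import ActivityVolume, GridSpec, _as_vec3

MEDIA = ("active", "air", "cold_water", "plastic")

# ---------------------------------------------------------------------------
# geometry constants (mm unless noted)
# ---------------------------------------------------------------------------

# NEMA NU 4-2008 IQ phantom
IQ_CHAMBER_DIAMETER = 33.5
IQ_CHAMBER_HEIGHT = 63.0
IQ_ROD_DIAMETERS = (5.0, 2.0, 4.0, 1.0, 3.0)  # angular order; ROIs must not overlap
IQ_ROD_RADIUS = 7.0              # rod centres from the phantom axis (NEMA NU 4)
IQ_ROD_SECTION_LENGTH = 20.0
IQ_INSERT_DIAMETER = 8.0
IQ_INSERT_HEIGHT = 14.0
IQ_INSERT_OFFSET = 7.5           # insert centres from the phantom axis
IQ_DEFAULT_ACTIVITY_MBQ = 3.7

# Micro-hollow-sphere phantom
MHS_CHAMBER_DIAMETER = 40.0
MHS_CHAMBER_HEIGHT = 82.0
MHS_SPHERE_DIAMETERS = (7.86, 6.23, 4.95, 3.95)
MHS_SPHERE_RING_RADIUS = 11.0    # mounting circle of the sphere centres
MHS_SPHERE_PLANE_Z = 20.0        # axial position of the sphere plane
MHS_BACKGROUND_VOI_Z = -20.0     # uniform-region VOI, away from the spheres

# Scattering source
SCATTER_DIAMETER = 4.0
SCATTER_HEIGHT = 90.0

# Rat phantom (cavity volumes in mL as printed; shapes are volume-matched
# primitives because only volumes and tumour diameters are published)
RAT_BODY_DIAMETER = 50.0
RAT_BODY_LENGTH = 110.0
RAT_ORGAN_VOLUMES_ML = {"liver": 5.6, "bladder": 0.2, "kidney_right": 0.6, "kidney_left": 0.7}
RAT_TUMOUR_POSITIONS = ("UL", "UR", "BL", "BR")
RAT_TUMOUR_DIAMETERS = {"UL": 10.0, "UR": 8.0, "BL": 10.0, "BR": 8.0}
RAT_TUMOUR_CENTRES = {
    "UL": (-14.0, 0.0, 28.0),
    "UR": (14.0, 0.0, 28.0),
    "BL": (-14.0, 0.0, -28.0),
    "BR": (14.0, 0.0, -28.0),
}
RAT_LIVER_CENTRE = (0.0, 0.0, 15.0)

DEFAULT_VOXEL_MM = 0.4125        # reconstructed pixel size of the scanner


def _sphere_radius_for_volume_ml(v_ml: float) -> float:
    return (3.0 * v_ml * 1000.0 / (4.0 * math.pi)) ** (1.0 / 3.0)


# ---------------------------------------------------------------------------
# primitives
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ShapePrimitive:
    """A geometric primitive with a fill concentration.

    ``concentration_bq_ml`` must be 0 for non-active media (air, cold water,
    plastic all rasterize to zero activity).  ``contained`` marks shapes that
    must lie inside the phantom's background chamber; standalone objects such
    as scattering sources set it to False.
    """

    kind: str                      # sphere | cylinder | box
    centre: tuple[float, float, float]
    concentration_bq_ml: float = 0.0
    medium: str = "active"
    radius: Optional[float] = None
    height: Optional[float] = None
    axis: int = 2                  # cylinder axis: 0=x, 1=y, 2=z (axial)
    edges: Optional[tuple[float, float, float]] = None
    name: str = ""
    contained: bool = True

    def __post_init__(self):
        if self.kind not in ("sphere", "cylinder", "box"):
            raise ValueError(f"unknown shape kind {self.kind!r}")
        if self.medium not in MEDIA:
            raise ValueError(f"unknown medium {self.medium!r}")
        if self.medium != "active" and self.concentration_bq_ml != 0.0:
            raise ValueError(f"{self.medium} shape {self.name!r} must have zero concentration")
        if self.concentration_bq_ml < 0:
            raise ValueError("concentration must be >= 0")
        object.__setattr__(self, "centre", tuple(float(c) for c in self.centre))
        if self.kind == "sphere":
            if self.radius is None or self.radius <= 0:
                raise ValueError("sphere needs radius > 0")
        elif self.kind == "cylinder":
            if self.radius is None or self.radius <= 0 or self.height is None or self.height <= 0:
                raise ValueError("cylinder needs radius > 0 and height > 0")
            if self.axis not in (0, 1, 2):
                raise ValueError("cylinder axis must be 0, 1 or 2")
        else:
            if self.edges is None or any(e <= 0 for e in self.edges):
                raise ValueError("box needs strictly positive edge lengths")

    # -- geometry ----------------------------------------------------------

    def volume_ml(self) -> float:
        if self.kind == "sphere":
            return 4.0 / 3.0 * math.pi * self.radius**3 / 1000.0
        if self.kind == "cylinder":
            return math.pi * self.radius**2 * self.height / 1000.0
        return float(np.prod(self.edges)) / 1000.0

    def bbox(self) -> tuple[np.ndarray, np.ndarray]:
        c = np.asarray(self.centre)
        if self.kind == "sphere":
            half = np.full(3, self.radius)
        elif self.kind == "cylinder":
            half = np.full(3, self.radius)
            half[self.axis] = self.height / 2.0
        else:
            half = np.asarray(self.edges) / 2.0
        return c - half, c + half

    def contains(self, x, y, z):
        """Vectorized membership test; x/y/z broadcast together (mm)."""
        cx, cy, cz = self.centre
        if self.kind == "sphere":
            return (x - cx) ** 2 + (y - cy) ** 2 + (z - cz) ** 2 <= self.radius**2
        if self.kind == "cylinder":
            coords = (x - cx, y - cy, z - cz)
            ax = coords[self.axis]
            others = [coords[i] for i in range(3) if i != self.axis]
            return (others[0] ** 2 + others[1] ** 2 <= self.radius**2) & (
                np.abs(ax) <= self.height / 2.0
            )
        ex, ey, ez = (e / 2.0 for e in self.edges)
        return (np.abs(x - cx) <= ex) & (np.abs(y - cy) <= ey) & (np.abs(z - cz) <= ez)

    def translated(self, offset: Sequence[float]) -> "ShapePrimitive":
        off = _as_vec3(offset)
        return replace(self, centre=tuple(np.asarray(self.centre) + off))


@dataclass(frozen=True)
class PhantomSpec:
    """An ordered list of primitives plus the main fillable chamber.

    ``background`` may be None for composite scenes (several animals in the
    field of view) in which case no containment validation is performed.
    """

    name: str
    shapes: tuple[ShapePrimitive, ...]
    background: Optional[ShapePrimitive] = None

    def __post_init__(self):
        object.__setattr__(self, "shapes", tuple(self.shapes))

    def all_shapes(self) -> tuple[ShapePrimitive, ...]:
        if self.background is None:
            return self.shapes
        return (self.background,) + self.shapes

    def bbox(self) -> tuple[np.ndarray, np.ndarray]:
        los, his = zip(*(s.bbox() for s in self.all_shapes()))
        return np.min(los, axis=0), np.max(his, axis=0)

    def translated(self, offset: Sequence[float]) -> "PhantomSpec":
        bg = self.background.translated(offset) if self.background is not None else None
        return PhantomSpec(
            name=self.name,
            shapes=tuple(s.translated(offset) for s in self.shapes),
            background=bg,
        )

    # -- serialization -----------------------------------------------------

    def to_dict(self) -> dict:
        def shape_dict(s: ShapePrimitive) -> dict:
            d = {
                "kind": s.kind,
                "centre": list(s.centre),
                "concentration_bq_ml": s.concentration_bq_ml,
                "medium": s.medium,
                "name": s.name,
                "contained": s.contained,
            }
            if s.kind == "sphere":
                d["radius"] = s.radius
            elif s.kind == "cylinder":
                d.update(radius=s.radius, height=s.height, axis=s.axis)
            else:
                d["edges"] = list(s.edges)
            return d

        out = {"name": self.name, "shapes": [shape_dict(s) for s in self.shapes]}
        if self.background is not None:
            out["background"] = shape_dict(self.background)
        return out

    @classmethod
    def from_dict(cls, d: dict) -> "PhantomSpec":
        def mk(sd: dict) -> ShapePrimitive:
            kw = dict(sd)
            kw["centre"] = tuple(kw["centre"])
            if "edges" in kw and kw["edges"] is not None:
                kw["edges"] = tuple(kw["edges"])
            return ShapePrimitive(**kw)

        bg = mk(d["background"]) if "background" in d and d["background"] else None
        return cls(name=d["name"], shapes=tuple(mk(s) for s in d["shapes"]), background=bg)


# ---------------------------------------------------------------------------
# rasterization
# ---------------------------------------------------------------------------

def default_grid(spec: PhantomSpec, voxel_mm: float | Sequence[float] = DEFAULT_VOXEL_MM,
                 margin_mm: float = 5.0) -> GridSpec:
    """Isocentre-symmetric grid covering ``spec``'s bounding box plus margin."""
    vs = np.broadcast_to(np.atleast_1d(np.asarray(voxel_mm, dtype=float)), (3,)).copy()
    lo, hi = spec.bbox()
    extent = 2.0 * np.maximum(np.abs(lo), np.abs(hi)) + 2.0 * margin_mm
    return GridSpec.centred(extent, vs)


def voxelize(spec: PhantomSpec, grid: GridSpec, supersample: int = 2,
             chunk_slices: int = 8) -> ActivityVolume:
    """Rasterize a phantom onto ``grid`` with sub-voxel averaging.

    Each voxel value is the mean concentration over ``supersample**3``
    regularly spaced sub-points; overlap is resolved last-shape-wins and
    non-active media rasterize to 0 Bq/mL.  Inserts flagged ``contained``
    must lie inside the background chamber (validated numerically here).
    """
    s = int(supersample)
    if s < 1:
        raise ValueError("supersample must be >= 1")
    lo_g, hi_g = grid.bounds
    lo_p, hi_p = spec.bbox() if spec.all_shapes() else (lo_g, hi_g)
    if spec.all_shapes() and (np.any(lo_p < lo_g - 1e-9) or np.any(hi_p > hi_g + 1e-9)):
        raise ValueError(
            "grid too small for phantom: required bounding box "
            f"x:[{lo_p[0]:.2f},{hi_p[0]:.2f}] y:[{lo_p[1]:.2f},{hi_p[1]:.2f}] "
            f"z:[{lo_p[2]:.2f},{hi_p[2]:.2f}] mm, grid covers "
            f"x:[{lo_g[0]:.2f},{hi_g[0]:.2f}] y:[{lo_g[1]:.2f},{hi_g[1]:.2f}] "
            f"z:[{lo_g[2]:.2f},{hi_g[2]:.2f}] mm"
        )

    nx, ny, nz = (int(d) for d in grid.dims)
    vx, vy, vz = grid.voxel_size
    # sub-point coordinates along each axis (length n*s)
    xs = grid.origin[0] + ((np.arange(nx * s) + 0.5) / s - 0.5) * vx
    ys = grid.origin[1] + ((np.arange(ny * s) + 0.5) / s - 0.5) * vy
    zs = grid.origin[2] + ((np.arange(nz * s) + 0.5) / s - 0.5) * vz

    shapes = spec.all_shapes()
    background = spec.background
    out = np.zeros(grid.shape, dtype=float)

    def sub_range(coords: np.ndarray, lo: float, hi: float) -> tuple[int, int]:
        """Index range of sub-points overlapping [lo, hi]."""
        i0 = int(np.searchsorted(coords, lo - 1e-12, side="left"))
        i1 = int(np.searchsorted(coords, hi + 1e-12, side="right"))
        return i0, i1

    for z0 in range(0, nz, chunk_slices):
        z1 = min(z0 + chunk_slices, nz)
        zsub = zs[z0 * s: z1 * s]
        ncz = z1 - z0
        field_chunk = np.zeros((ncz * s, ny * s, nx * s), dtype=float)
        bg_mask_chunk = None
        if background is not None:
            bg_mask_chunk = background.contains(
                xs[None, None, :], ys[None, :, None], zsub[:, None, None]
            )
            if background.medium == "active" and background.concentration_bq_ml > 0:
                field_chunk[bg_mask_chunk] = background.concentration_bq_ml

        for shape in (spec.shapes if background is not None else shapes):
            (blo, bhi) = shape.bbox()
            ix0, ix1 = sub_range(xs, blo[0], bhi[0])
            iy0, iy1 = sub_range(ys, blo[1], bhi[1])
            iz0, iz1 = sub_range(zsub, blo[2], bhi[2])
            if ix0 >= ix1 or iy0 >= iy1 or iz0 >= iz1:
                continue
            m = shape.contains(
                xs[ix0:ix1][None, None, :],
                ys[iy0:iy1][None, :, None],
                zsub[iz0:iz1][:, None, None],
            )
            m = np.broadcast_to(m, (iz1 - iz0, iy1 - iy0, ix1 - ix0))
            if shape.contained and bg_mask_chunk is not None:
                outside = m & ~bg_mask_chunk[iz0:iz1, iy0:iy1, ix0:ix1]
                if outside.any():
                    raise ValueError(
                        f"insert {shape.name or shape.kind!r} extends outside the "
                        f"background chamber of phantom {spec.name!r}"
                    )
            sub = field_chunk[iz0:iz1, iy0:iy1, ix0:ix1]
            sub[m] = shape.concentration_bq_ml if shape.medium == "active" else 0.0

        out[z0:z1] = field_chunk.reshape(ncz, s, ny, s, nx, s).mean(axis=(1, 3, 5))

    return ActivityVolume(values=out, grid=grid, radionuclide="none", time_offset_min=0.0,
                          meta={"phantom": spec.name, "supersample": s})


# ---------------------------------------------------------------------------
# phantom builders
# ---------------------------------------------------------------------------

def iq_rod_centres() -> list[tuple[float, tuple[float, float]]]:
    """(diameter, (x, y)) of the five hot rods, centred phantom."""
    out = []
    for k, d in enumerate(IQ_ROD_DIAMETERS):
        ang = math.radians(90.0 + k * 72.0)
        out.append((d, (IQ_ROD_RADIUS * math.cos(ang), IQ_ROD_RADIUS * math.sin(ang))))
    return out


def nema_iq_fillable_volume_ml() -> float:
    """Closed-form fillable volume of the IQ phantom (chamber minus PMMA plug
    plus drilled rods minus the two cold inserts)."""
    r = IQ_CHAMBER_DIAMETER / 2.0
    chamber = math.pi * r**2 * IQ_CHAMBER_HEIGHT
    plug = math.pi * r**2 * IQ_ROD_SECTION_LENGTH
    rods = sum(math.pi * (d / 2.0) ** 2 * IQ_ROD_SECTION_LENGTH for d in IQ_ROD_DIAMETERS)
    inserts = 2.0 * math.pi * (IQ_INSERT_DIAMETER / 2.0) ** 2 * IQ_INSERT_HEIGHT
    return (chamber - plug + rods - inserts) / 1000.0


def _make_nema_iq(activity_mbq: float = IQ_DEFAULT_ACTIVITY_MBQ,
                  background_bq_ml: Optional[float] = None) -> PhantomSpec:
    if background_bq_ml is None:
        background_bq_ml = activity_mbq * 1e6 / nema_iq_fillable_volume_ml()
    h = IQ_CHAMBER_HEIGHT
    chamber = ShapePrimitive(
        kind="cylinder", centre=(0, 0, 0), radius=IQ_CHAMBER_DIAMETER / 2.0, height=h,
        concentration_bq_ml=background_bq_ml, name="chamber",
    )
    z_plug = -h / 2.0 + IQ_ROD_SECTION_LENGTH / 2.0
    shapes = [
        ShapePrimitive(kind="cylinder", centre=(0, 0, z_plug), radius=IQ_CHAMBER_DIAMETER / 2.0,
                       height=IQ_ROD_SECTION_LENGTH, medium="plastic", name="pmma_plug"),
    ]
    for d, (x, y) in iq_rod_centres():
        shapes.append(ShapePrimitive(
            kind="cylinder", centre=(x, y, z_plug), radius=d / 2.0,
            height=IQ_ROD_SECTION_LENGTH, concentration_bq_ml=background_bq_ml,
            name=f"rod_{d:g}mm",
        ))
    z_ins = h / 2.0 - IQ_INSERT_HEIGHT / 2.0
    shapes.append(ShapePrimitive(kind="cylinder", centre=(IQ_INSERT_OFFSET, 0, z_ins),
                                 radius=IQ_INSERT_DIAMETER / 2.0, height=IQ_INSERT_HEIGHT,
                                 medium="air", name="insert_air"))
    shapes.append(ShapePrimitive(kind="cylinder", centre=(-IQ_INSERT_OFFSET, 0, z_ins),
                                 radius=IQ_INSERT_DIAMETER / 2.0, height=IQ_INSERT_HEIGHT,
                                 medium="cold_water", name="insert_water"))
    return PhantomSpec(name="nema_nu4_iq", shapes=tuple(shapes), background=chamber)


def mhs_sphere_centres() -> list[tuple[float, tuple[float, float, float]]]:
    """(inner diameter, centre) of the four hollow spheres, centred phantom."""
    out = []
    for k, d in enumerate(MHS_SPHERE_DIAMETERS):
        ang = math.radians(45.0 + k * 90.0)
        out.append((d, (MHS_SPHERE_RING_RADIUS * math.cos(ang),
                        MHS_SPHERE_RING_RADIUS * math.sin(ang), MHS_SPHERE_PLANE_Z)))
    return out


def mhs_net_chamber_volume_ml() -> float:
    chamber = math.pi * (MHS_CHAMBER_DIAMETER / 2.0) ** 2 * MHS_CHAMBER_HEIGHT / 1000.0
    spheres = sum(4.0 / 3.0 * math.pi * (d / 2.0) ** 3 / 1000.0 for d in MHS_SPHERE_DIAMETERS)
    return chamber - spheres


def _make_mhs(background_activity_mbq: float = 4.0,
              sphere_bq_ml: Optional[float] = None,
              contrast_ratio: Optional[float] = None) -> PhantomSpec:
    """MHS phantom.  Give either ``sphere_bq_ml`` or a ``contrast_ratio``
    (background:sphere, e.g. 1/8 means spheres are 8x hotter)."""
    if sphere_bq_ml is not None and contrast_ratio is not None:
        raise ValueError("give either an explicit sphere concentration or a contrast "
                         "ratio, not both")
    bg = background_activity_mbq * 1e6 / mhs_net_chamber_volume_ml()
    if sphere_bq_ml is None:
        if contrast_ratio is None:
            contrast_ratio = 1.0 / 8.0
        sphere_bq_ml = bg / contrast_ratio
    chamber = ShapePrimitive(kind="cylinder", centre=(0, 0, 0),
                             radius=MHS_CHAMBER_DIAMETER / 2.0, height=MHS_CHAMBER_HEIGHT,
                             concentration_bq_ml=bg, name="chamber")
    shapes = [
        ShapePrimitive(kind="sphere", centre=c, radius=d / 2.0,
                       concentration_bq_ml=sphere_bq_ml, name=f"sphere_{d:g}mm")
        for d, c in mhs_sphere_centres()
    ]
    return PhantomSpec(name="mhs", shapes=tuple(shapes), background=chamber)


def _make_line_source(concentration_mbq_ml: float = 0.5, length_mm: float = 1.0,
                      centre=(0.0, 0.0, 0.0)) -> PhantomSpec:
    """A short 1 mm ID capillary segment along the axial direction.

    The default 1 mm length keeps the axial profile of the blurred image
    peaked so that all three NEMA resolution directions are measurable.
    """
    src = ShapePrimitive(kind="cylinder", centre=tuple(centre), radius=0.5,
                         height=length_mm, axis=2,
                         concentration_bq_ml=concentration_mbq_ml * 1e6,
                         name="capillary", contained=False)
    return PhantomSpec(name="line_source", shapes=(src,), background=None)


def _make_scatter_cylinder(activity_mbq: float = 4.0,
                           centre=(0.0, 0.0, 0.0)) -> PhantomSpec:
    vol_ml = math.pi * (SCATTER_DIAMETER / 2.0) ** 2 * SCATTER_HEIGHT / 1000.0
    cyl = ShapePrimitive(kind="cylinder", centre=tuple(centre),
                         radius=SCATTER_DIAMETER / 2.0, height=SCATTER_HEIGHT,
                         concentration_bq_ml=activity_mbq * 1e6 / vol_ml,
                         name="scatter_source", contained=False)
    return PhantomSpec(name="scatter_cylinder", shapes=(cyl,), background=None)


def _make_rat(tumour_mbq_ml: Sequence[float] = (0.3, 0.6, 1.2, 2.4),
              liver_mbq_ml: float = 0.3, kidney_mbq_ml: float = 1.2,
              bladder_mbq_ml: float = 2.4, include_bladder: bool = True) -> PhantomSpec:
    """Anatomical rat phantom.  ``tumour_mbq_ml`` is in (UL, UR, BL, BR) order."""
    if len(tumour_mbq_ml) != 4:
        raise ValueError("need four tumour concentrations (UL, UR, BL, BR)")
    body = ShapePrimitive(kind="cylinder", centre=(0, 0, 0), radius=RAT_BODY_DIAMETER / 2.0,
                          height=RAT_BODY_LENGTH, medium="plastic", name="body")
    shapes = [
        ShapePrimitive(kind="sphere", centre=(-7.0, 0.0, 38.0), radius=6.0,
                       medium="air", name="lung_left"),
        ShapePrimitive(kind="sphere", centre=(7.0, 0.0, 38.0), radius=6.0,
                       medium="air", name="lung_right"),
        ShapePrimitive(kind="sphere", centre=RAT_LIVER_CENTRE,
                       radius=_sphere_radius_for_volume_ml(RAT_ORGAN_VOLUMES_ML["liver"]),
                       concentration_bq_ml=liver_mbq_ml * 1e6, name="liver"),
        ShapePrimitive(kind="sphere", centre=(8.0, 0.0, -5.0),
                       radius=_sphere_radius_for_volume_ml(RAT_ORGAN_VOLUMES_ML["kidney_right"]),
                       concentration_bq_ml=kidney_mbq_ml * 1e6, name="kidney_right"),
        ShapePrimitive(kind="sphere", centre=(-8.0, 0.0, -5.0),
                       radius=_sphere_radius_for_volume_ml(RAT_ORGAN_VOLUMES_ML["kidney_left"]),
                       concentration_bq_ml=kidney_mbq_ml * 1e6, name="kidney_left"),
    ]
    if include_bladder:
        shapes.append(ShapePrimitive(
            kind="sphere", centre=(0.0, 0.0, -40.0),
            radius=_sphere_radius_for_volume_ml(RAT_ORGAN_VOLUMES_ML["bladder"]),
            concentration_bq_ml=bladder_mbq_ml * 1e6, name="bladder"))
    for pos, conc in zip(RAT_TUMOUR_POSITIONS, tumour_mbq_ml):
        shapes.append(ShapePrimitive(
            kind="sphere", centre=RAT_TUMOUR_CENTRES[pos],
            radius=RAT_TUMOUR_DIAMETERS[pos] / 2.0,
            concentration_bq_ml=conc * 1e6, name=f"tumour_{pos}"))
    return PhantomSpec(name="rat", shapes=tuple(shapes), background=body)


_BUILDERS = {
    "nema_nu4_iq": _make_nema_iq,
    "mhs": _make_mhs,
    "line_source": _make_line_source,
    "rat": _make_rat,
    "scatter_cylinder": _make_scatter_cylinder,
}


def make_phantom(name: str, **params) -> PhantomSpec:
    """Build one of the study phantoms by name.

    See the module docstring for the available phantoms and the builder
    functions for their parameters (printed units: MBq and MBq/mL).
    """
    try:
        builder = _BUILDERS[name]
    except KeyError:
        raise ValueError(f"unknown phantom {name!r}; available: {sorted(_BUILDERS)}") from None
    return builder(**params)


# ---------------------------------------------------------------------------
# multi-animal arrangement
# ---------------------------------------------------------------------------

def arrange_multi_animal(spec: PhantomSpec, offset_mm: Sequence[float],
                         n_scatter: int = 3, scatter_activity_mbq: float = 4.0) -> PhantomSpec:
    """Translate the measurement phantom transaxially and add scattering
    sources at the remaining quadrant positions (the four-animal layout).

    With offset (ox, oy) the scatter cylinders occupy (-ox, oy), (-ox, -oy)
    and (ox, -oy); all centre-to-centre transaxial distances of the resulting
    square layout equal 2*|offset| per side.
    """
    if n_scatter not in (0, 1, 2, 3):
        raise ValueError("n_scatter must be between 0 and 3")
    ox, oy = (float(v) for v in np.asarray(offset_mm, dtype=float).reshape(2))
    moved = spec.translated((ox, oy, 0.0))
    if n_scatter == 0:
        return moved

    main_radius = None
    if spec.background is not None and spec.background.kind == "cylinder":
        main_radius = spec.background.radius
    else:
        lo, hi = spec.bbox()
        main_radius = float(np.max(hi[:2] - lo[:2]) / 2.0)

    scatter_positions = [(-ox, oy), (-ox, -oy), (ox, -oy)][:n_scatter]
    shapes = list(moved.shapes)
    for i, (sx, sy) in enumerate(scatter_positions):
        dist = math.hypot(sx - ox, sy - oy)
        if dist < main_radius + SCATTER_DIAMETER / 2.0:
            raise ValueError(
                f"scatter source {i} at ({sx:g}, {sy:g}) mm overlaps the measurement "
                f"phantom at ({ox:g}, {oy:g}) mm"
            )
        scat = _make_scatter_cylinder(activity_mbq=scatter_activity_mbq,
                                      centre=(sx, sy, 0.0))
        shapes.extend(replace(s, name=f"{s.name}_{i}") for s in scat.shapes)
    return PhantomSpec(name=f"{spec.name}_multi", shapes=tuple(shapes),
                       background=moved.background)
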