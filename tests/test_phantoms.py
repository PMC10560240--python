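"""Phantom geometry and rasterization."""

import math

import numpy as np
import pytest

from petquant import GridSpec, PhantomSpec, ShapePrimitive, make_phantom, voxelize
from petquant.phantoms import (MHS_SPHERE_DIAMETERS, arrange_multi_animal,
                               default_grid, mhs_net_chamber_volume_ml,
                               mhs_sphere_centres)


def lone(shape: ShapePrimitive, name="test") -> PhantomSpec:
    return PhantomSpec(name=name, shapes=(shape,), background=None)


class TestVoxelize:
    @pytest.mark.parametrize("diameter", [10.0, 8.0])
    def test_sphere_integral_matches_closed_form(self, diameter):
        """Rasterized sphere volume converges to (pi/6) d^3 (< 1% error)."""
        sphere = ShapePrimitive(kind="sphere", centre=(0, 0, 0), radius=diameter / 2,
                                concentration_bq_ml=1.0, contained=False)
        grid = GridSpec.centred((diameter + 4,) * 3, (0.2, 0.2, 0.2))
        vol = voxelize(lone(sphere), grid, supersample=4)
        truth_ml = math.pi / 6 * diameter**3 / 1000.0
        assert vol.total_activity_bq == pytest.approx(truth_ml, rel=1e-3)

    def test_cylinder_integral_matches_closed_form(self):
        """The MHS background cylinder (40 mm ID x 82 mm) integrates to
        pi r^2 h = 103.04 mL within 0.5%."""
        cyl = ShapePrimitive(kind="cylinder", centre=(0, 0, 0), radius=20.0,
                             height=82.0, concentration_bq_ml=1.0, contained=False)
        grid = GridSpec.centred((50, 50, 92), (0.5, 0.5, 0.5))
        vol = voxelize(lone(cyl), grid, supersample=4)
        assert vol.total_activity_bq == pytest.approx(math.pi * 4.0 * 8.2, rel=5e-3)

    def test_empty_phantom_rasterizes_to_zero(self):
        bg = ShapePrimitive(kind="cylinder", centre=(0, 0, 0), radius=5, height=10,
                            concentration_bq_ml=0.0)
        spec = PhantomSpec(name="empty", shapes=(), background=bg)
        vol = voxelize(spec, GridSpec.centred((12, 12, 12), (1, 1, 1)), supersample=2)
        assert np.all(vol.values == 0)

    def test_last_shape_wins(self):
        """Rasterizing [A, B] where B covers A equals rasterizing [B] inside B."""
        a = ShapePrimitive(kind="sphere", centre=(0, 0, 0), radius=3,
                           concentration_bq_ml=5.0, contained=False)
        b = ShapePrimitive(kind="sphere", centre=(0, 0, 0), radius=4,
                           concentration_bq_ml=2.0, contained=False)
        grid = GridSpec.centred((12, 12, 12), (0.5, 0.5, 0.5))
        both = voxelize(PhantomSpec("ab", (a, b)), grid, supersample=2)
        only_b = voxelize(PhantomSpec("b", (b,)), grid, supersample=2)
        assert np.array_equal(both.values, only_b.values)

    def test_translation_equivariance_integer_voxels(self):
        src = ShapePrimitive(kind="sphere", centre=(0, 0, 0), radius=2.2,
                             concentration_bq_ml=1.0, contained=False)
        grid = GridSpec.centred((20, 20, 20), (1, 1, 1))
        base = voxelize(lone(src), grid, supersample=3)
        shifted = voxelize(lone(src.translated((3, 0, -2))), grid, supersample=3)
        # +3 voxels in x (last array axis), -2 in z (first axis)
        rolled = np.roll(np.roll(base.values, 3, axis=2), -2, axis=0)
        assert np.allclose(shifted.values, rolled, atol=1e-12)

    def test_nonactive_media_rasterize_to_zero(self):
        bg = ShapePrimitive(kind="cylinder", centre=(0, 0, 0), radius=6, height=12,
                            concentration_bq_ml=7.0)
        hole = ShapePrimitive(kind="sphere", centre=(0, 0, 0), radius=2, medium="air")
        vol = voxelize(PhantomSpec("p", (hole,), background=bg),
                       GridSpec.centred((14, 14, 14), (0.5, 0.5, 0.5)), supersample=2)
        assert vol.values[vol.grid.index_of((0, 0, 0))] == 0.0
        assert vol.values[vol.grid.index_of((0, 0, 4.8))] == 7.0

    def test_insert_outside_background_raises_with_name(self):
        bg = ShapePrimitive(kind="cylinder", centre=(0, 0, 0), radius=5, height=10,
                            concentration_bq_ml=1.0)
        stray = ShapePrimitive(kind="sphere", centre=(7, 0, 0), radius=1,
                               concentration_bq_ml=2.0, name="stray_insert")
        with pytest.raises(ValueError, match="stray_insert"):
            voxelize(PhantomSpec("p", (stray,), background=bg),
                     GridSpec.centred((20, 20, 20), (0.5, 0.5, 0.5)), supersample=1)

    def test_grid_too_small_reports_required_bbox(self):
        big = ShapePrimitive(kind="sphere", centre=(0, 0, 0), radius=30,
                             concentration_bq_ml=1.0, contained=False)
        with pytest.raises(ValueError, match="required bounding box"):
            voxelize(lone(big), GridSpec.centred((20, 20, 20), (1, 1, 1)))


class TestMakePhantom:
    def test_unknown_name(self):
        with pytest.raises(ValueError, match="unknown phantom"):
            make_phantom("nope")

    def test_mhs_contrast_from_background_activity(self):
        """4 MBq background with 0.3 MBq/mL spheres gives ~1:8 contrast."""
        spec = make_phantom("mhs", background_activity_mbq=4.0, sphere_bq_ml=0.3e6)
        bg = spec.background.concentration_bq_ml
        ratio = 0.3e6 / bg
        assert 7.5 <= ratio <= 8.5

    def test_mhs_ratio_and_explicit_concentration_conflict(self):
        with pytest.raises(ValueError, match="not both"):
            make_phantom("mhs", sphere_bq_ml=1e5, contrast_ratio=1 / 8)

    def test_mhs_contrast_ratio_sets_sphere_concentration(self):
        spec = make_phantom("mhs", contrast_ratio=1 / 4)
        bg = spec.background.concentration_bq_ml
        sphere = next(s for s in spec.shapes if s.kind == "sphere")
        assert sphere.concentration_bq_ml == pytest.approx(4 * bg)
        assert {s.radius * 2 for s in spec.shapes} == set(MHS_SPHERE_DIAMETERS)

    def test_line_source_is_single_axial_millimetre_cylinder(self):
        spec = make_phantom("line_source")
        assert len(spec.shapes) == 1
        src = spec.shapes[0]
        assert src.kind == "cylinder" and src.axis == 2
        assert src.radius * 2 == pytest.approx(1.0)

    def test_rat_uniform_fill_gives_unit_tumour_liver_ratio(self):
        spec = make_phantom("rat", tumour_mbq_ml=(0.3, 0.3, 0.3, 0.3))
        liver = next(s for s in spec.shapes if s.name == "liver")
        for s in spec.shapes:
            if s.name.startswith("tumour"):
                assert s.concentration_bq_ml == pytest.approx(liver.concentration_bq_ml)

    def test_rat_printed_volumes(self):
        spec = make_phantom("rat")
        vols = {s.name: s.volume_ml() for s in spec.shapes}
        assert vols["liver"] == pytest.approx(5.6, rel=1e-6)
        assert vols["bladder"] == pytest.approx(0.2, rel=1e-6)
        assert vols["tumour_UL"] == pytest.approx(math.pi / 6 * 1.0, rel=1e-6)
        no_bladder = make_phantom("rat", include_bladder=False)
        assert not any(s.name == "bladder" for s in no_bladder.shapes)

    def test_roundtrip_serialization(self):
        spec = make_phantom("nema_nu4_iq")
        assert PhantomSpec.from_dict(spec.to_dict()) == spec


class TestArrangeMultiAnimal:
    def test_zero_offset_identity(self):
        spec = make_phantom("mhs")
        assert arrange_multi_animal(spec, (0, 0), n_scatter=0) == spec.translated((0, 0, 0))

    def test_quadrant_layout_distances(self):
        """Four objects at (+-50, +-50): side-adjacent centres are 100 mm apart."""
        scene = arrange_multi_animal(make_phantom("mhs"), (50, 50), n_scatter=3)
        centres = [scene.background.centre[:2]]
        centres += [s.centre[:2] for s in scene.shapes if "scatter" in s.name]
        assert len(centres) == 4
        dists = sorted(math.hypot(a[0] - b[0], a[1] - b[1])
                       for i, a in enumerate(centres) for b in centres[i + 1:])
        assert np.allclose(dists[:4], 100.0) and np.allclose(dists[4:], 100 * math.sqrt(2))

    def test_scatter_total_activity(self):
        """Each rasterized scattering source carries ~4 MBq."""
        scat = make_phantom("scatter_cylinder", activity_mbq=4.0)
        grid = GridSpec.centred((10, 10, 96), (0.25, 0.25, 0.5))
        vol = voxelize(scat, grid, supersample=4)
        assert vol.total_activity_bq == pytest.approx(4e6, rel=1e-2)

    def test_overlap_raises(self):
        with pytest.raises(ValueError, match="overlap"):
            arrange_multi_animal(make_phantom("mhs"), (10, 10), n_scatter=3)

    def test_invalid_n_scatter(self):
        with pytest.raises(ValueError):
            arrange_multi_animal(make_phantom("mhs"), (50, 50), n_scatter=4)
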