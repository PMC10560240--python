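"""NEMA NU 4 image-quality metrics: uniformity, spill-over, rod recovery."""

import numpy as np
import pytest

from petquant import (ActivityVolume, GridSpec, ScannerPreset, VOISpec,
                      make_phantom, reformat_axial, rod_recovery, spillover,
                      simulate_acquisition, uniformity_metrics, voxelize)
from petquant.nema_iq import iq_layout, propagate_rc_sd, voi_statistics
from petquant.phantoms import default_grid
from petquant.workflows import iq_analysis


def cube_volume(values):
    values = np.asarray(values, dtype=float)
    grid = GridSpec.centred(np.array(values.shape)[::-1] * 1.0, (1, 1, 1))
    return ActivityVolume(values=values, grid=grid)


class TestUniformity:
    def test_constant_field(self, uniform_volume):
        voi = VOISpec(shape="cylinder", centre=(0, 0, 0), radius=5, height=8)
        res = uniformity_metrics(uniform_volume, voi)
        assert res.pct_sd == 0.0
        assert res.minimum == res.maximum == res.mean == 100.0

    def test_population_sd_convention(self):
        """Toy 4-voxel VOI {1,1,3,3}: mean 2, population SD 1, %SD 50."""
        vol = cube_volume(np.full((7, 7, 7), 9.0))
        iz = iy = ix = 3
        vol.values[iz - 2: iz + 2, iy, ix] = [1.0, 1.0, 3.0, 3.0]
        voi = VOISpec(shape="cylinder", centre=(0, 0, -0.5), radius=0.5, height=4.0)
        res = voi_statistics(vol, voi)
        assert res.n_voxels == 4
        assert res.mean == pytest.approx(2.0)
        assert res.sd == pytest.approx(1.0)      # population, not sample
        assert res.pct_sd == pytest.approx(50.0)

    def test_minimum_voxel_guard(self, uniform_volume):
        voi = VOISpec(shape="sphere", centre=(0, 0, 0), radius=1.2)
        with pytest.raises(ValueError, match="voxels"):
            uniformity_metrics(uniform_volume, voi)

    def test_voi_outside_grid_rejected(self, uniform_volume):
        voi = VOISpec(shape="cylinder", centre=(10, 0, 0), radius=5, height=8)
        with pytest.raises(ValueError, match="outside"):
            uniformity_metrics(uniform_volume, voi)

    def test_noise_level_read_back(self):
        """Injected 5.55% relative noise reads back as %SD ~ 5.55."""
        from petquant import NoiseModel, add_noise
        grid = GridSpec.centred((40, 40, 40), (1, 1, 1))
        vol = ActivityVolume(values=np.full(grid.shape, 1000.0), grid=grid)
        noisy = add_noise(vol, NoiseModel(level=0.0555, seed=11))
        voi = VOISpec(shape="cylinder", centre=(0, 0, 0), radius=15, height=20)
        assert uniformity_metrics(noisy, voi).pct_sd == pytest.approx(5.55, abs=0.3)


class TestSpillover:
    def make_insert_volume(self, air_frac, water_frac, bg=100.0):
        vol = cube_volume(np.full((20, 20, 20), bg))
        air = VOISpec(shape="cylinder", centre=(5, 0, 0), radius=2, height=8)
        water = VOISpec(shape="cylinder", centre=(-5, 0, 0), radius=2, height=8)
        vol.values[air.mask(vol.grid)] = air_frac * bg
        vol.values[water.mask(vol.grid)] = water_frac * bg
        return vol, air, water

    def test_five_percent_insert_reads_exactly(self):
        vol, air, water = self.make_insert_volume(0.05, 0.10)
        bg_voi = VOISpec(shape="cylinder", centre=(0, 6, 0), radius=3, height=10)
        bg = uniformity_metrics(vol, bg_voi)
        res = spillover(vol, air, water, bg)
        assert res.sor_air == pytest.approx(0.05, abs=1e-12)
        assert res.sor_water == pytest.approx(0.10, abs=1e-12)

    def test_insert_equal_to_background_gives_unity(self):
        vol, air, water = self.make_insert_volume(1.0, 1.0)
        bg = uniformity_metrics(vol, VOISpec(shape="cylinder", centre=(0, 6, 0),
                                             radius=3, height=10))
        res = spillover(vol, air, water, bg)
        assert res.sor_air == pytest.approx(1.0) and res.sor_water == pytest.approx(1.0)

    def test_perfect_cold_insert_gives_zero(self):
        vol, air, water = self.make_insert_volume(0.0, 0.0)
        bg = uniformity_metrics(vol, VOISpec(shape="cylinder", centre=(0, 6, 0),
                                             radius=3, height=10))
        res = spillover(vol, air, water, bg)
        assert res.sor_air == 0.0 and res.sor_water == 0.0

    def test_scaling_invariance(self):
        vol, air, water = self.make_insert_volume(0.07, 0.2)
        bg_voi = VOISpec(shape="cylinder", centre=(0, 6, 0), radius=3, height=10)
        res1 = spillover(vol, air, water, uniformity_metrics(vol, bg_voi))
        scaled = vol.with_values(vol.values * 37.3)
        res2 = spillover(scaled, air, water, uniformity_metrics(scaled, bg_voi))
        assert res2.sor_air == pytest.approx(res1.sor_air, rel=1e-12)


class TestReformatAxial:
    def test_single_slice_identity(self, uniform_volume):
        uniform_volume.values[5] += np.arange(24 * 24).reshape(24, 24)
        z = uniform_volume.grid.coords(2)[5]
        slab = reformat_axial(uniform_volume, 1.0, z)
        assert np.array_equal(slab.values[0], uniform_volume.values[5])

    def test_two_slice_mean(self, uniform_volume):
        uniform_volume.values[5] = 10.0
        uniform_volume.values[6] = 30.0
        zc = uniform_volume.grid.coords(2)[5:7].mean()
        slab = reformat_axial(uniform_volume, 2.0, zc)
        assert np.allclose(slab.values[0], 20.0)

    def test_axially_constant_volume(self, uniform_volume):
        slab = reformat_axial(uniform_volume, 10.0, 0.0)
        assert np.allclose(slab.values[0], 100.0)

    def test_slab_outside_volume_raises(self, uniform_volume):
        with pytest.raises(ValueError, match="slab"):
            reformat_axial(uniform_volume, 4.0, 100.0)


class TestRodRecovery:
    def test_sd_rc_hand_example(self):
        """RC 0.8 with relative SDs 0.03 and 0.04 propagates to SD_RC 0.04."""
        assert propagate_rc_sd(0.8, 3.0, 100.0, 4.0, 100.0) == pytest.approx(0.04)
        assert propagate_rc_sd(0.8, 0.0, 100.0, 0.0, 100.0) == 0.0

    def test_perfect_image_recovers_unity_with_zero_sd(self, identity_preset):
        spec = make_phantom("nema_nu4_iq")
        grid = default_grid(spec, 0.4125)
        vol = simulate_acquisition(spec, grid, identity_preset, radionuclide="none",
                                   supersample=2)
        layout = iq_layout()
        bg = uniformity_metrics(vol, layout.uniformity_voi)
        for rod in rod_recovery(vol, layout.rods, bg, layout.rod_slab_centre_mm):
            assert rod.rc == pytest.approx(1.0, abs=1e-9)
            assert rod.sd_rc == pytest.approx(0.0, abs=1e-12)

    def test_rc_increases_with_rod_diameter_under_blur(self, mild_preset):
        """Partial-volume ordering of the five rods (1 through 5 mm)."""
        spec = make_phantom("nema_nu4_iq")
        grid = default_grid(spec, 0.4125)
        vol = simulate_acquisition(spec, grid, mild_preset, radionuclide="none",
                                   supersample=2)
        report = iq_analysis(vol)
        by_diam = sorted(report.rods, key=lambda r: r.diameter_mm)
        rcs = [r.rc for r in by_diam]
        assert rcs == sorted(rcs)
        assert rcs[0] < 0.9  # the 1 mm rod is strongly partial-volume limited
        assert all(r.sd_rc >= 0 for r in by_diam)

    def test_rc_scale_invariance(self, mild_preset):
        spec = make_phantom("nema_nu4_iq")
        grid = default_grid(spec, 0.825)
        vol = simulate_acquisition(spec, grid, mild_preset, radionuclide="none",
                                   supersample=2)
        layout = iq_layout()
        bg = uniformity_metrics(vol, layout.uniformity_voi)
        r1 = rod_recovery(vol, layout.rods, bg, layout.rod_slab_centre_mm)
        scaled = vol.with_values(vol.values * 5.0)
        bg2 = uniformity_metrics(scaled, layout.uniformity_voi)
        r2 = rod_recovery(scaled, layout.rods, bg2, layout.rod_slab_centre_mm)
        for a, b in zip(r1, r2):
            assert b.rc == pytest.approx(a.rc, rel=1e-12)
            assert b.sd_rc == pytest.approx(a.sd_rc, rel=1e-6, abs=1e-9)

    def test_overlapping_rois_warn(self, uniform_volume):
        bg = uniformity_metrics(uniform_volume,
                                VOISpec(shape="cylinder", centre=(0, 0, 0),
                                        radius=5, height=8))
        rods = [(3.0, (0.0, 0.0)), (3.0, (4.0, 0.0))]
        with pytest.warns(UserWarning, match="overlap"):
            rod_recovery(uniform_volume, rods, bg, slab_centre_mm=0.0,
                         slab_thickness_mm=4.0)
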