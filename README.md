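# petquant

Digital-phantom PET simulation and NEMA NU 4-2008 quantification analysis for
small-animal imaging on clinical SiPM-based scanners.

## The problem

Dedicated small-animal PET cameras are expensive and scarce; modern clinical
SiPM-based PET/CT systems resolve well enough (≈1.8 mm FWHM with
PSF-modelling reconstruction) that rats can be imaged — even four at a time,
exploiting the large field of view — and quantified on them.  Establishing
that requires the standard preclinical quality-control battery: spatial
resolution from 1 mm capillaries, NEMA NU 4-2008 image quality (uniformity,
spill-over, rod recovery), partial-volume recovery coefficients on a
micro-hollow-sphere (MHS) phantom, and an end-to-end quantification check on
an anatomical rat phantom with decaying tumour activities.

`petquant` implements that battery as a reusable, tested pipeline.  Physical
acquisitions are replaced by a digital-phantom simulator that emulates the
*post-reconstruction* image: sub-voxel rasterization of the phantom geometry,
radionuclide decay to the acquisition start, a Gaussian positron-range
kernel per nuclide (18F ≪ 68Ga), an effective scanner PSF with optional
difference-of-Gaussians ringing (the overshoot of unregularized PSF
reconstructions that drives recovery coefficients above 1), an optional
Gaussian post-filter and reproducible voxel noise.  The analysis layer is
scanner-agnostic and works on any NIfTI volume in Bq/mL.

## The metrics

* **Resolution** — profiles through the line-source maximum in the radial,
  tangential and axial directions; the apex is refined by a parabolic fit
  through the three highest samples and FWHM/FWTM are obtained by linear
  interpolation at half / tenth maximum (NEMA NU 4-2008).
* **Image quality** — uniformity %SD = 100·SD/mean in a 22 mm × 10 mm
  cylindrical VOI; spill-over ratios SOR = Mean_insert / Mean_background for
  the air and cold-water inserts (4 mm × 7.5 mm VOIs); rod recovery
  RC_rod = max pixel of the rod / Mean_background on a 10 mm axial slab, with
  SD_RC = RC·√((SD_lp/Mean_lp)² + (SD_bg/Mean_bg)²) propagated from a 10 mm
  axial line profile.
* **Sphere recovery** — RC_max = A_max / A_true and RC_A50 = A50 / A_true,
  where A50 averages the 26-connected component above the background-adapted
  threshold T = B + 0.5·(A_max − B) (EANM-style 50% isocontour).
* **Agreement** — per-tumour A_max/A50 vs the decay-corrected truth
  A_calc = A_fill·exp(−ln2·t/T½); Pearson r and Bland–Altman bias ± 1.96 SD
  of the percent differences.

## Worked example

```python
from petquant import workflows

# Micro-hollow-sphere phantom, 1/8 background:sphere contrast, 18F,
# PSF reconstruction + 2 mm Gaussian filter, one noise realization.
for r in workflows.mhs_recovery("vision450_psf_filtered", "F18",
                                contrast_ratio=1/8, seed=7):
    print(f"{r.diameter_mm:4.2f} mm  RC_max {r.rc_max:4.2f}  RC_A50 {r.rc_a50:4.2f}")

res = workflows.measure_line_source_resolution("vision450_psf_centred")
print({k: round(float(v), 2) for k, v in res.fwhm.items()})
```

prints

```
7.86 mm  RC_max 1.01  RC_A50 0.78
6.23 mm  RC_max 0.97  RC_A50 0.72
4.95 mm  RC_max 0.84  RC_A50 0.62
3.95 mm  RC_max 0.68  RC_A50 0.50
{'radial': 1.8, 'tangential': 1.8, 'axial': 1.84}
```

Both recovery coefficients fall with sphere size — the partial-volume effect
at work: the 3.95 mm sphere is barely twice the system resolution, so only
half of its true concentration survives in the 50% isocontour mean.  The
resolution readout returns the preset's calibrated 1.80 mm width.

The same functionality is exposed on the command line:

```bash
petquant simulate --phantom mhs --preset vision450_psf_filtered --out mhs.nii.gz
petquant quantify --preset vision450_psf_filtered --report rc.csv
petquant resolution --in line.nii.gz --report res.json
petquant run --config study.yaml --out reports/
```

## Layout

| module | contents |
| --- | --- |
| `petquant.phantoms` | phantom geometry primitives, the four study phantoms, sub-voxel rasterization, multi-animal arrangement |
| `petquant.simulate` / `presets` / `nuclides` | scanner presets (with NEMA-capillary width calibration), positron range, PSF + ringing, noise, decay |
| `petquant.resolution` | NEMA line-source FWHM/FWTM analysis |
| `petquant.nema_iq` | uniformity, spill-over, rod recovery with error propagation |
| `petquant.spheres` | background-adapted 50% isocontour and sphere RCs |
| `petquant.rat_study` | decaying rat-phantom series, tumour quantification, Pearson / Bland–Altman agreement |
| `petquant.io` / `workflows` / `cli` | NIfTI + sidecar I/O, end-to-end study drivers, command line |

See `docs/methods.md` for the model assumptions, calibration details and
known limitations.
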