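# Methods

## Image-formation model

The simulator produces the *reconstructed* PET volume directly; there is no
sinogram, listmode, TOF or iterative-reconstruction stage.  A simulated
acquisition is the composition

1. **Rasterization.** Phantoms are ordered lists of analytic primitives
   (spheres, cylinders, boxes) with fill concentrations in Bq/mL; later
   shapes override earlier ones, which is how cold inserts and drilled rods
   are carved out of a hot chamber.  Each voxel averages `supersample³`
   regularly spaced sub-points (default 2 for simulations, 4 for geometry
   checks), so integrated activities converge to the closed-form volumes of
   the primitives; at supersample 4 and voxels ≤ radius/5 the relative error
   is below 1%.  Inserts are validated numerically to lie inside the
   background chamber.
2. **Decay.** All concentrations scale by exp(−ln2·t/T½) from calibration to
   acquisition start; T½ = 109.77 min (18F) and 67.71 min (68Ga).
3. **Positron range.** An isotropic Gaussian per nuclide (default FWHM
   0.5 mm for 18F, 2.4 mm for 68Ga, user-overridable).  True annihilation
   kernels are cusp-like bi-exponentials; a Gaussian is adequate here
   because only the qualitative 68Ga degradation (larger spill-over, lower
   recovery) needs to be reproduced, not a specific kernel shape.
4. **Scanner PSF.** An isotropic Gaussian kernel; with ringing amplitude
   a > 0 the kernel becomes (1+a)·G(f) − a·G(2f) (unit integral), whose
   negative side-lobe produces the edge overshoot characteristic of
   unregularized PSF-modelling reconstructions and lets recovery
   coefficients exceed 1.  An optional Gaussian post-filter follows, the
   standard regularization for quantification-oriented reconstructions.
5. **Noise.** Voxelwise Gaussian noise with SD = level × (uniform-compartment
   reference), reproducible under a seed.  The reference is the median of
   the positive voxels of the *pre-blur* rasterized truth: the uniform
   background dominates the hot volume in every study phantom, so the median
   sits on its plateau and is insensitive both to small hot structures
   (spheres, scattering sources) and to blur tails.  A scaled-Poisson mode
   (`Poisson(v/c)·c`) is available for count-limited emulation.

Attenuation and scatter are assumed perfectly corrected, as CT-based
corrections are applied on the real system; scattering sources therefore
influence results only through placement geometry and the noise model.
Blurring uses reflective edge padding and conserves interior activity to
better than 0.1%.

## Scanner presets and the capillary calibration

A preset condenses a scanner + reconstruction combination into
(psf_fwhm, ringing_amplitude, positron ranges, noise_rel_sd,
post_filter_fwhm).  Shipped presets for a clinical SiPM PET/CT:

| preset | width (mm) | noise %SD | notes |
| --- | --- | --- | --- |
| `vision450_psf_centred` | 1.80 | 5.55 | PSF reconstruction, centre of FOV |
| `vision450_psf_offcentre` | 1.78 | 5.55 | PSF reconstruction, 5 cm off-centre |
| `vision450_osem` | 3.13 | 2.69 | 3D-OSEM |
| `vision450_fbp` | 3.86 | — | filtered backprojection |
| `vision450_psf_ringing` | 1.80 | 5.55 | adds a = 0.6 edge ringing |
| `vision450_psf_filtered` | 1.80 | 5.55 | adds a 2 mm Gaussian post-filter |

**Width semantics.** NEMA NU 4 resolutions are measured with 1 mm
inner-diameter capillaries filled with 18F, so a published width already
folds in the source diameter, the 18F positron range, the reconstructed
pixel footprint and the estimator's interpolation bias.  Shipped presets
store that *measured* width (`fwhm_is_measured=True`); the intrinsic kernel
the simulator applies is solved from an operational forward model — the
transaxial profile of a uniform 1 mm disc convolved with the total blur
(semi-analytic chord integral), convolved with the 0.4125 mm voxel
footprint, sampled at the voxel pitch and measured with the packaged
parabolic-apex / linear-interpolation estimator — with the 18F positron
range then removed in quadrature.  Re-measuring a simulated capillary
therefore returns the stored width (1.80 mm is read back as 1.799 mm), and
user presets constructed by hand default to raw-kernel semantics.  The
`ref_sor` field carries published spill-over fractions per nuclide used by
constructed-image checks; noise_rel_sd is calibrated to the published
uniformity %SD for 18F and is the only free noise parameter (the source
material reports no other noise figures).

## Phantom geometry

Dimensions are the printed ones; undimensioned details are fixed here:

* **NEMA NU 4 IQ phantom** — 33.5 mm ID × 63 mm chamber; 20 mm PMMA rod
  section with 1–5 mm rods at the NEMA 7 mm mounting radius, angular order
  (5, 2, 4, 1, 3) mm so the 2×-diameter analysis ROIs do not overlap; air and
  cold-water inserts 8 mm ID × 14 mm at ±7.5 mm.  Default fill 3.7 MBq over
  the fillable volume.  Wall thicknesses are ignored throughout (walls are
  not dimensioned in the source material).
* **MHS phantom** — 40 mm ID × 82 mm cylinder; hollow spheres of 7.86 /
  6.23 / 4.95 / 3.95 mm inner diameter on an 11 mm ring at +20 mm axially;
  the uniformity VOI sits at −20 mm.  Sphere stems are omitted.  With a
  contrast ratio r the sphere concentration is r⁻¹ × background, where the
  background concentration is the fill activity over the net chamber volume.
* **Line source** — 1 mm ID capillary segment along the scanner axis.  The
  default length is 1 mm so the axial profile remains peaked and all three
  NEMA directions are measurable from one volume; an axially long capillary
  has no axial falloff.  Transaxial widths are independent of the length
  (the blur is separable).
* **Rat phantom** — 50 mm × 110 mm plastic body; lungs as two air spheres;
  liver / bladder / kidney cavities as spheres of the printed volumes (5.6 /
  0.2 / 0.6+0.7 mL — only volumes are printed, so volume-matched primitives
  stand in for the CT-derived organ meshes); four tumour spheres of 10 / 10 /
  8 / 8 mm at the UL/BL (left, 10 mm) and UR/BR (right, 8 mm) positions.
  Organ fills 0.3 / 2.4 / 1.2 MBq/mL (liver / bladder / kidneys); tumour
  fills 0.3 / 0.6 / 1.2 / 2.4 MBq/mL cyclically rotated across the four
  rats; the bladder is present in two of the four rats.
* **Multi-animal layout** — the measurement phantom moves to a transaxial
  offset (default (50, 50) mm) and up to three 4 mm ID × 90 mm scattering
  cylinders (4 MBq each) occupy the remaining quadrants; side-adjacent
  centres are then 100 mm apart.

Coordinates are right-handed (x radial-at-centre, y tangential, z axial),
mm units, volumes stored axial-slowest; the default grid is isotropic
0.4125 mm (the scanner's reconstructed pixel size; the axial spacing is
configurable).

## Analysis conventions

* All VOI statistics use the **population** SD and voxel-centre membership
  (no partial-voxel weighting; VOIs are large relative to voxels).
* Resolution profiles are single-voxel-wide lines with **no background
  subtraction** (sources are in air).  Off-centred sources rotate the
  radial/tangential directions about the FOV axis with bilinear resampling
  at the transaxial pitch.  Peak ties resolve to the lexicographically
  smallest (z, y, x) index.
* The rod slab is a 10 mm axial **mean** (values stay in Bq/mL); rod ROIs
  are circles of twice the rod diameter; the RC error bar propagates the
  relative SDs of the 10 mm axial line profile and of the background in
  quadrature.
* The 50% isocontour is **background-adapted**: T = B + 0.5·(A_max − B),
  the standard adaptive-threshold form of the EANM FDG guideline (the
  adaptation formula is not written out in the source material; this choice
  is an assumption).  The mask is the 26-connected component containing the
  maximum, ties at T included, clipped to a search VOI of twice the sphere
  diameter centred on the known position (simulator geometry; no image
  registration).  A structure whose maximum does not exceed the background
  (within a 10⁻⁹ relative tie tolerance) is flagged undetectable.
* Rat-study background for the A50 adaptation is the per-rat **liver VOI
  mean** (5 mm radius sphere at the liver centre).  A direct consequence is
  that tumours filled at liver concentration (the 0.3 MBq/mL position, 20 of
  the 80 tumour rows) are flagged undetectable and excluded from agreement
  statistics with a logged count.
* Bland–Altman percent differences are referenced to the truth
  (d = 100·(measured − A_calc)/A_calc) with limits of agreement
  bias ± 1.96 × sample SD; Pearson r and r² are both reported.

## What the simulator does and does not establish

Passing tests show that the analysis layer reads back exactly what the
simulator put in (preset widths, noise levels, spill-over fractions,
geometry) and that the metric formulas behave as derived (monotone
partial-volume loss, nuclide ordering, error propagation, decay identities).
They do not validate the scanner physics itself: real reconstructions have
spatially varying, non-Gaussian PSFs, correlated noise, residual scatter and
attenuation artefacts, and real phantoms have walls, stems and filling
imperfections.  Published scanner-specific figures (e.g. recovery curves
measured on hardware) enter only as calibrated preset parameters, never as
simulation outputs.

## Numerical choices and problem sizes

* Rasterization is chunked along the axial axis with per-shape bounding-box
  clipping; memory stays below a few hundred MB at the native grid.
* The capillary-calibration solver brackets the total blur with Brent's
  method to 10⁻⁶ mm; profiles are evaluated on a 5 µm grid and results are
  cached per preset.
* The width estimator requires the peak strictly inside the profile and
  raises "profile truncated" when a threshold is never crossed; it biases
  wide at coarse sampling (≈ +1% at 0.4125 mm for a 1.8 mm FWHM; worse below
  ~4 samples per FWHM), which the operational calibration absorbs.
* Standard problem sizes: line-source grids 24 mm cubes; IQ phantom
  ≈ 106×106×177 voxels; the multi-animal MHS comparison runs two
  ≈ 364×364×232 simulations (≈ 30 s each on one CPU).  Unit tests use
  coarser 0.6–1.5 mm grids where only orderings or identities are asserted.

## Known limitations

* No sinogram/listmode/TOF simulation, detector geometry, sensitivity or
  count-rate (NECR) modelling; no CT simulation or attenuation maps.
* Positron range and PSF are stationary and isotropic; real off-centre
  astigmatism is represented only by a separate preset.
* The gaussian_relative noise model is white; reconstructed PET noise is
  spatially correlated, so matched noise magnitudes do not imply matched
  noise texture.
* The anatomical rat phantom uses volume-matched primitive organs, not the
  CT-derived meshes of the physical object.
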