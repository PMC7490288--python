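# Methods

## Phantom

The anatomy is a geometric surrogate for an MRI-derived parcellation,
built from nested ellipsoids on a 128 × 128 × 63 grid with
2.682 × 2.682 × 2.425 mm voxels (field of view ≈ 343 × 343 × 153 mm).
From outside in: a CSF shell (3 mm), a cortical grey-matter ribbon, and a
white-matter core containing a ventricular CSF ellipsoid and three pairs of
subcortical grey blobs (hippocampus, parahippocampal gyrus, fusiform,
mutually adjacent and clipped to the white-matter core). A separate
cerebellar ellipsoid splits into a grey shell (7 mm) and a white core. The
cortical ribbon is partitioned into frontal, parietal, occipital and
middle+inferior-temporal sectors by elevation/azimuth angles; laterality is
exact mirror symmetry about the mid-sagittal plane. The build is
deterministic in (preset, grid, seed); the seed drives a ≤1 mm
mirror-symmetric jitter of the blob centres. This reproduces the spill-over
topology that drives the PVE — thin grey matter sandwiched between hotter
white matter and cold CSF — without claiming anatomical realism: no gyri,
no sulci, and a much coarser region set than a FreeSurfer parcellation.

Presets: `HC` uses a 6.0 mm cortical ribbon; `AD` thins it to 4.2 mm and
shrinks the hippocampus axes by 0.75 (≈0.42 volume ratio), emulating
atrophy. Ribbon thicknesses are above anatomical cortical thickness
(~2.5-3 mm) by design: at this voxel pitch a 3 mm ribbon would be a single
broken voxel layer, while 4-6 mm keeps every region connected and still
PVE-dominated (thickness below the PSF width).

True-SUVR tables (overridable) carry the tau-tracer signature: high
non-specific white-matter binding (HC 1.8 / AD 2.0), cortical grey 1.0-1.2
(HC), elevated temporal/hippocampal uptake in AD (1.8-2.4), CSF 0.05,
cerebellar grey exactly 1.0 after reference normalization. One consequence
matters for interpretation: with white matter hotter than most grey
regions, spill-in and spill-out nearly cancel in some cortical ROIs, so a
few uncorrected %differences are close to zero (±3%), whereas a clinical
tau phantom with real atrophy shows large underestimation everywhere. The
qualitative pass/fail structure of "every correction improves every ROI"
depends on this contrast (see Limitations).

The attenuation map is two-valued: 0.096 cm⁻¹ in all brain tissue and
0.144 cm⁻¹ in a 2-voxel skull shell grown morphologically around the brain.

## Simulator

Slice-wise 2-D parallel-beam projection (180 angles over 180°, radial bins
= in-plane matrix size, inscribed-circle geometry) with Beer-Lambert
attenuation factors from the μ-map; line integrals are in SUVR·mm. A
scatter surrogate (heavily smoothed attenuated trues, 25% of total) and a
constant randoms background (15%) are added, counts are drawn as
Poisson(noise_scale · total)/noise_scale, and the *known* backgrounds are
subtracted and attenuation correction applied — the precorrection design:
the backgrounds cancel exactly in the mean and only shape the noise.
Negative net bins are kept; clipping would break FBP linearity.
`noise_scale = 0.4` makes the Poisson-noise standard deviation in the
cerebellar-grey ROI ≈6% of its mean, a typical static-brain-PET level.

Reconstruction is slice-wise FBP with a ramp filter cut at Nyquist, no
apodization, followed by a 3-D Gaussian post-filter (6 mm FWHM). Because
the slice-wise FBP blurs only in-plane (≈3.05 mm from the ramp cutoff and
back-projection interpolation at the default grid), the post-filter is by
default widened along z to √(6² + 3.05²) mm so the chain's point response
is isotropic — the situation a fully 3-D reconstruction produces and the
isotropic-PSF correction model assumes (`ReconConfig.harmonize_axial`).

The effective resolution is *measured*, not assumed: a point source pushed
through the noiseless chain and fitted with an isotropic 3-D Gaussian
(amplitude, centre, sigma, offset; nonlinear least squares in a 25 mm
window) gives 6.63 mm FWHM at the default configuration. That value is
handed to the corrections as the "true" FWHM. The fit slightly
underestimates the region-scale blur because the ramp point response has
negative sidelobes a Gaussian cannot follow; this leaves the GTM family
with ideal-condition residuals of roughly ±1-2%. The point response is
also mildly shift-variant (±0.2 mm across the field of view); only the
central value is used.

An `image-space` simulation mode (Gaussian blur + optional white noise)
exists for fast, exactly-Gaussian unit tests.

## Corrections

All algorithms share one substrate: region spread functions
RSF_j = Gaussian(FWHM) ⊗ indicator(region j), computed with zero-padded
boundaries, plus an explicit background region so the model is complete on
reconstructed images. Matrix solves are direct, with the condition number
checked against a configurable threshold (default 10⁸) and no
regularization — a failure is informative in an error-propagation study.
Negative corrected voxels are retained; uncorrectable voxels (MG grey
recovery below threshold, vanishing Yang denominator) are NaN and excluded
from ROI means.

* **GTM** solves ω t = b with ω_ij the mean of RSF_j over region i; exact
  for piecewise-constant activity under a matched PSF.
* **Labbé** fits the observed image as Σ_j t_j·RSF_j by least squares over
  the modelled voxels (per-voxel source, per-region target).
* **MG** removes the white-matter (and, default, CSF) spill-in estimated by
  a class-level GTM solve and divides by the grey recovery RSF_GM, on
  voxels with RSF_GM ≥ 0.5 (default; 2- and 3-compartment modes provided).
  MG does not model spill between different grey regions, which leaves
  percent-level residuals wherever neighbouring grey regions differ.
* **RBV** paints the GTM means into a synthetic image s and applies the
  Yang ratio image·s/(PSF ⊗ s) voxel-wise.
* **IY** iterates the Yang ratio from observed regional means, re-measuring
  means each pass; ten iterations is the conventional operating point. The
  fixed point is exact, but convergence is slow where a thin region abuts a
  near-zero one (CSF at 0.05): after ten iterations ~4-5% residual remains
  in the thinnest AD cortex.
* **SFS-RR** decomposes the observed and a synthetic structural image with
  a 4-level 3-D separable discrete wavelet transform (`db2`; PyWavelets
  `wavedecn`/`waverecn`, padded and cropped internally) and blends the
  detail subbands, keeping the functional approximation band. The default
  rule mixes a fixed structural fraction of 0.34 into every detail subband
  (roughly one third structural information); a `per_subband_fit` rule
  instead uses the least-squares projection coefficient of the functional
  detail onto the structural detail, clipped to [0, 1]. The original
  formulation uses a dual-tree complex wavelet transform and a published
  weighting scheme; this separable-DWT blend is a documented surrogate with
  the weighting exposed as a knob. Base SFS-RR builds the structural image
  from observed ROI means — a convex blend toward a structural image whose
  ROI means equal the (biased) observed means, so its ROI-level recovery is
  modest by construction; **mod SFS-RR** uses GTM means instead and
  recovers substantially more.

The correctors are scikit-learn-style estimators (`fit(parcellation)`
precomputes the RSF stack and transfer matrix; `transform(volume)` applies
the correction), so a fitted object can be reused across scenarios and the
RSF stack shared between algorithms.

## Error injection

FWHM mismatch is a parameter pass-through. Misregistration translates the
anatomical side (labels, nearest-neighbour, exactly one resampling) while
the PET stays fixed — equivalent to shifting either modality, and it avoids
interpolating PET intensities. Volume mis-segmentation grows or shrinks a
region one 6-connected shell at a time with deterministic partial-shell
selection (distance from the region centroid, ties by voxel index); grown
voxels are taken from adjacent labels (never a region's last voxel),
removed voxels go to the nearest surviving label, so the brain mask is
conserved; the achieved ratio must be within 5% of the target factor. All
perturbations are deterministic.

## Experiment driver and operating sizes

One pseudo-observed image per (condition, seed) is reused across all
scenario cells, so cell differences reflect only the injected error. ROI
analysis unites left/right hemispheres except for X-translations (which
break the symmetry); for translation and segmentation scenarios both the
true-anatomy and the erroneous-anatomy ROI template are evaluated.
ROI-based solvers are sampled through their painted synthetic image so the
two templates genuinely disagree; with the aligned template this equals the
solved means exactly. The true ROI value is always the truth-image value
under the true template. Per-cell failures are recorded in a `status`
column and the run continues.

Default problem sizes: the full grid (128 × 128 × 63) for the factorial
study and acceptance checks (a complete noiseless two-condition
ideal+mismatch study runs in ~1 minute on one core); a half-resolution grid
with the same field of view for unit tests; slab toys for the brute-force
oracle comparisons. Multiple noise realizations are supported but the
default is a single realization per condition, matching the n = 1 study
design.

## Known limitations

* Geometry is ellipsoidal; regional adjacency, not anatomy, is modelled.
  Absolute %differences are specific to this phantom's contrast and do not
  transfer to clinical values.
* Because some ROIs sit near the spill-in/spill-out cancellation point,
  "every algorithm improves every ROI under ideal conditions" holds for
  GTM, Labbé, RBV and mod SFS-RR but fails by 0.3-2 points for MG, IY and
  base SFS-RR in the two or three near-zero-error ROIs — their own
  ideal-condition residuals (documented above) exceed an uncorrected error
  of only ±3%. Likewise |%difference| is not strictly monotone in the FWHM
  mismatch wherever the signed error crosses zero between mismatch levels;
  the growth tendency holds away from those crossings. The acceptance tests
  assert the strict properties and these cells fail them, deliberately.
* The scatter surrogate is parametric, not physical; it only shapes noise.
* The PSF handed to corrections is isotropic and shift-invariant; the
  simulated chain is close to, but not exactly, Gaussian.
* 2-D slice-wise projection: no oblique rays, no scanner-specific effects
  (normalization, dead time, decay).
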