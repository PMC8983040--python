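# Methods

## Scope and model

`centropol` quantifies rotational asymmetry of centrioles from
multichannel 3D fluorescence stacks, as acquired by ultrastructure
expansion microscopy (U-ExM).  A centriole is modelled as a ninefold
ring of microtubule-triplet rods of radius ~115 nm (pre-expansion) and
length 320–430 nm, carrying a rotationally asymmetric luminal marker at
its distal end: two consecutive triplets labelled at an intensity ratio
of ~1.5 (the brighter triplet is numbered 1, its counterclockwise
neighbour 2, in the distal view), on top of a faint full-length
wall-associated component on all nine triplets.  Optional structures are
a basal-foot lobe (offset 25° clockwise from the axis opposite the
marker), a distal-appendage ring, and an orthogonal procentriole
attached at the proximal region of the parent.

The analysis chain mirrors single-particle averaging practice:

1. **Verticalization** — rotate the volume (trilinear resampling in
   physical space, honouring anisotropic z pitch) so the long axis maps
   to +z.  The axis comes either from two annotated points or from the
   principal axis of the intensity-weighted second-moment tensor of the
   Otsu-thresholded wall channel.
2. **Ring fit** — algebraic (Kasa) least-squares circle through ≥3
   annotated triplet-ring landmarks.  The Kasa solution differs from
   geometric least squares by O(σ²/r), negligible at annotation noise
   levels; a zooming grid-search geometric fit serves as the test oracle.
3. **Rotational reference** — one azimuth per particle: the intensity
   centroid of the top-q% voxels (q = 5) of the marker channel in the
   distal 30% of the z-frame ("brightest" mode), or an annotated point
   (manual, basal-foot, or C-end reference).  Azimuths are degrees
   counterclockwise from +x in the distal view; a proximal-view flag
   negates them exactly.
4. **Standardization** — an in-plane similarity transform (rotation
   sending the reference azimuth to 0°, scale sending the fitted radius
   to the canonical 115 nm, translation to the canonical axis) plus a
   linear axial map of the z-frame onto the canonical axial span,
   resampled trilinearly onto a 96×96×64 canonical grid at 5 nm
   pre-expansion lateral pitch.  Voxels sampled outside the source are
   masked, never zero-filled.  A "native" axial mode (translation only)
   exists for length-sensitive analyses; the default rescales, reading
   the z-frame as defining the axial extent.
5. **Averaging** — voxelwise mask-aware mean, SD and count over
   particles (West's incremental scheme; unweighted by default, with an
   optional per-particle weighting flag).
6. **Azimuthal profile** — mean intensity per 1° bin in a radial annulus
   (default 0.6–1.0× canonical radius, the luminal side) and axial
   window (default distal 30%); empty bins are filled by circular
   interpolation.  Per-triplet means are taken in a narrow ±5° window at
   each triplet azimuth — deliberately narrower than the 40° sector, so
   a bright lobe does not bleed into its neighbour's readout.  The
   `triplet_excess_ratio` readout subtracts the median of the remaining
   triplets (the faint-wall pedestal) before forming ratios.

Morphometry operates outside the canonical frame: interpeak distance d
from per-channel line profiles with 3-point parabolic subpixel
refinement (prominence gate 3× the profile MAD); centriole length from
half-maximum crossings of the wall channel's axial profile (daughter
mode) or proximal half-maximum to distal-appendage axial peak (mother
mode); focus intensity as a disk sum across the z-series minus the
median-annulus background (median, not mean, to resist bleed-through
from neighbouring centrioles).  All nm outputs divide by the gel
expansion coefficient, so they scale exactly as 1/expansion.

Angular statistics follow the quadrant convention: relative angles are
measured clockwise from the reference (Q1 = [−45°, 45°) about it,
Q2 = [45°, 135°) clockwise, and so on, half-open and left-inclusive so a
boundary angle falls in the higher quadrant), binned and tested against
uniformity with Pearson's χ² on 3 df.  p-values are reported raw; a
Bonferroni flag exists for multi-panel runs.  Circular summaries include
the angle-doubled (axial) resultant for bimodal Q1/Q3-type alignment,
and a two-sample Kolmogorov–Smirnov comparison serves the interpeak-d
contrasts.

## Synthetic data: what it emulates and what it does not

The generator renders geometry pre-expansion in nm, scales it by the
gel expansion factor (default 4.0, a typical U-ExM coefficient), poses
it in 3D (tilt, tilt direction, in-plane rotation, translation), splats
point emitters trilinearly, convolves with an anisotropic Gaussian PSF
(defaults 80 nm lateral / 200 nm axial in expanded space, Airyscan-like)
and applies Poisson photon noise plus Gaussian read noise.  The photon
scale is set so the reference-channel peak carries `peak_snr²` expected
photons (default peak SNR 10).  Voxel pitch defaults to 30 nm lateral /
100 nm axial in expanded space.  Defaults for the geometry follow the
standard centriole dimensions (ring radius 115 nm; mother length 427 nm,
daughter 320 nm, procentriole 100 nm; distal marker occupying the distal
quarter at 0.8× the ring radius; faint wall component at 0.1 of the
triplet-1 amplitude).  Cohorts jitter length (SD 56 nm), radius (10%),
intensity (10%) and pose; per-particle seeds derive from
`SeedSequence([master, index])` so any particle is regenerable alone.

Not emulated: vectorial or depth-dependent PSFs, gel distortion
(anisotropic expansion), chromatic offsets, background structures, or
appendage blade morphology.  Passing tests therefore demonstrate the
pipeline's correctness on geometrically faithful, optically simplified
data — not robustness to the full failure modes of real acquisitions.

## The tilt/PSF interaction and the acquisition emulation

The axial PSF (σ ≈ 200 nm) is comparable to the marker's distance from
the axis (≈ 460 nm expanded).  For a tilted particle the blur ellipsoid
is tilted relative to the verticalized frame, so the distal z-window
cuts the marker's blurred cloud obliquely and displaces its lateral
centroid; image-based reference azimuths acquire biases of tens of
degrees at 20–30° tilt, independent of SNR.  This is a property of the
optics, not of the estimator: it is precisely why averaging acquisitions
select centrioles nearly perpendicular to the imaging plane.
`ParamJitter.near_perpendicular()` (tilt ≤ 5°) emulates that selection
and is the condition under which image-referenced averaging and azimuth
recovery are evaluated; landmark-based rotation/scale recovery is
evaluated up to 30° tilt, where it is exact by construction.  A unit
test pins the noise-only azimuth scatter (≈0.4° RMS at SNR 10, tilt 0),
and the acceptance suite the ≤5°-tilt condition (≈5° RMS).

## Statistical calibration choices

* The χ² p-value uses `scipy.stats.chi2.sf`; the closed-form df = 3
  survival function 2(1−Φ(√x)) + √(2x/π)e^(−x/2) is the independent
  oracle (agreement to 1e-10).
* Power for the Q2-depleted effect (quadrant odds 4/13, 1/13, 4/13,
  4/13) is Monte-Carlo; at n = 50 the exact multinomial enumeration
  gives 0.762.  The noncentral-χ² approximation (λ = n·Σ(pᵢ−¼)²/¼ ≈ 8)
  gives 0.653 — a first-order check only, since expected counts in the
  depleted quadrant fall below 5 at this n.
* "Flat within noise" for the unregistered control average is judged
  against a rotational null: the RMS deviation-from-flat of the same
  per-particle profiles re-averaged under fresh uniform rotations.  This
  null contains both photon noise and the finite-n rotational residual
  (≈ contrast/√n), which dominates at n = 34; a photon-noise-only floor
  would misclassify every finite cohort as structured.
* The averaging signal-to-noise gain is measured against the
  across-particle bin scatter, not the off-peak profile SD: the ninefold
  faint-wall ripple is common to all registered particles and is
  structure, not noise.

## Numerical details

* Trilinear interpolation throughout (`scipy.ndimage`); verticalization
  short-circuits bit-exactly when the axis is already +z.
* Welford/West accumulation for mean and SD; SD forced to 0 where only
  one particle contributes; mean undefined (NaN) where none does.
* Peak refinement clamps the parabolic offset to ±0.5 samples; a peak on
  a profile boundary is an error, not a truncated estimate.
* Degenerate inputs raise typed errors naming the particle and field:
  collinear ring landmarks, inverted z-frames, isotropic moment tensors
  (judged on the covariance whitened by the bounding-box moments, so a
  structureless volume is rejected regardless of box aspect), empty
  reference channels, zero-length frames.
* Exact ties in the top-q% selection are resolved by the deterministic
  voxel ordering of the flattened array; with continuous intensities
  they do not occur.

## Problem sizes

Cohort sizes follow the measurements they exercise: 34 particles for the
registered centrosome average, 35 for the basal-foot-referenced
multiciliated-cell average (20 replicate cohorts), 100 particles for
standardization recovery, 130 diplosomes per cohort (6 replicates) for
the end-to-end quadrant recovery, n = 40/2000 and n = 50/1000 for χ²
type-I and power calibration, and 40 mothers for length morphometry.
Unit tests use shorter, coarser-pitch renders where the property under
test does not depend on resolution.

## Known limitations

* The brightest-part reference is a top-q% centroid; its value on a
  two-lobe pattern sits between the lobes (≈16° from the brighter lobe
  at ratio 1.5), so registered averages peak near, not exactly at,
  triplet 1's azimuth.  The acceptance checks account for this by
  predicting the lobe position from the centroid offset.
* Image-based azimuths degrade with tilt (see above); the pipeline does
  not attempt PSF-aware deconvolution or tilt correction beyond rigid
  verticalization.
* The procentriole azimuth estimator assumes a single procentriole
  outside 1.25× the parent ring radius in the proximal half-frame.
* Axial rescaling of the z-frame standardizes away true length
  variation; use the "native" axial mode when absolute axial geometry
  matters.
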