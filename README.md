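# centropol

Rotational-asymmetry analysis of centrioles from 3D fluorescence stacks.

Centrioles are ninefold-symmetric microtubule-triplet cylinders, yet
several luminal proteins decorate them asymmetrically — enriched on one
or two consecutive triplets at the distal end.  Detecting and
quantifying that rotational polarity from expansion-microscopy (U-ExM)
z-stacks requires standardizing individual centrioles into a common
frame before averaging: verticalize each particle, fit the triplet ring,
fix a rotational reference, and map everything onto a canonical grid.
`centropol` implements that pipeline for microscopists and image
analysts, together with the measurements built on it and a synthetic
U-ExM generator with exhaustive ground truth so every stage is testable
without real data.

## What it computes

* **Standardization** — for particle *i* with fitted ring centre *cᵢ*,
  radius *rᵢ* and reference azimuth *φᵢ*, the in-plane similarity
  `x ↦ s·R(−φᵢ)(x − cᵢ) + c₀` with `s = r₀/rᵢ`, composed with
  verticalization and an affine axial map of the annotated z-frame —
  the reference lands at azimuth 0°, the ring on the canonical circle.
* **Particle averaging** — mask-aware voxelwise mean/SD/count over
  standardized particles; azimuthal intensity profile `I(θ)` in a
  luminal annulus with per-triplet readout (triplets numbered
  counterclockwise from the signal in the distal view).
* **Morphometry** — interpeak distance *d* = |x̂_protein − x̂_centre|/k
  (subpixel parabolic peaks, expansion coefficient *k*), centriole
  length from half-maximum crossings of the axial wall profile, and
  background-subtracted focus intensities.
* **Angular statistics** — relative angles measured clockwise from a
  reference, quadrant counts (Q2 = 45–135° clockwise), Pearson χ²
  against uniformity on 3 df, circular/axial resultants, two-sample
  Kolmogorov–Smirnov, and Monte-Carlo calibration of test power.
* **Synthetic centrioles** — posed, PSF-blurred, Poisson+read-noise
  renders of the triplet ring, two-lobe distal marker (ratio 1.5),
  basal foot, appendages and orthogonal procentrioles, with every
  generative parameter recorded as ground truth.

## Worked example

Render a small cohort, register it by the brightest marker region, and
read out the azimuthal asymmetry of the average:

```python
import centropol as cp

base = cp.preset_centriole()                      # two-lobe marker, ratio 1.5
jit = cp.ParamJitter.near_perpendicular()         # tilt <= 5 deg acquisition
pairs = cp.generate_cohort(base, 34, jit, seed=201)

can, parts = cp.CanonicalFrame(), []
for i, (stack, truth) in enumerate(pairs):
    ann = truth.to_annotation(f"p{i}", reference_mode="brightest")
    parts.append(cp.standardize(stack, ann, can)[0])

model = cp.average_standardized(parts)
prof = cp.azimuthal_profile(model, triplet1_azimuth_deg=344.1)
print(f"peak azimuth {prof.peak_azimuth_deg:.1f} deg, "
      f"triplet ratio {cp.triplet_excess_ratio(prof, 1, 2):.2f}")
```

```
peak azimuth 345.8 deg, triplet ratio 1.44
```

The peak sits within two degrees of the predicted triplet-1 position
(344.1° = the brighter lobe's offset from the two-lobe intensity
centroid that the registration reference tracks), and the
triplet-1/triplet-2 intensity ratio recovers the generative 1.5 within
a few percent — the brighter triplet carries ~50% more signal than its
counterclockwise neighbour.  Quadrant statistics work the same way from
angle tables:

```python
import numpy as np
rng = np.random.default_rng(0)
angles = cp.sample_quadrant_angles((4/13, 1/13, 4/13, 4/13), 130, rng)
counts, test = cp.quadrant_chi2(angles)
print(counts.counts, f"p = {test.p_value:.2g}")
```

```
(37, 8, 38, 47) p = 7.5e-06
```

A command-line front end mirrors the library:
`centropol simulate|standardize|average|profile|length|polarity --help`.

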