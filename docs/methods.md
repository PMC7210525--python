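# Methods

## Problem and model

A macular SD-OCT B-scan shows a hyper-reflective retinal band on a dark
vitreous/background; diabetic macular edema (DME) appears as hypo-reflective
fluid pockets inside the band. The pipeline segments those pockets in two
stages.

**Stage 1 (retina).** Lloyd's K-means with K = 2 on the 1-D intensity
distribution. The algorithm runs value-weighted on the intensity histogram
(cost independent of image size once the histogram is built) with
deterministic initialization — centers at the minimum and maximum observed
intensity — so repeated runs are bit-identical; random seeding would add
run-to-run variability the method does not need. Iteration stops at an exact
assignment fixed point (both K-means invariants then hold exactly) or when
the largest center shift drops below `tol`. The retina mask is the brighter
cluster after hole filling and largest-8-connected-component selection, with
holes filled again; filling *before* component selection matters because
fluid pockets are dark and would otherwise be excised from the retina that
Stage 2 must search. The scalar reference C is the mean image intensity over
the retina mask. C is interpreted as a region-mean intensity (mode
`roi_mean`) because Stage 2 uses it arithmetically alongside the interior
mean c₁; the mean of the background is exposed as an alternative
(`background_mean`) for comparison, but the retina mean is the default — it
is the only intensity statistic of the "region enclosed by the outer retinal
curve" that Stage 1 produces.

**Stage 2 (fluid).** A level-set contour φ (φ > 0 interior) evolves by an
explicit-Euler balloon step φ ← φ + dt·α·spf(I)·|∇φ| followed by
selective-binary + Gaussian regularization: φ is replaced by its ±1 sign map
and convolved with a Gaussian of standard deviation σ (kernel truncated at
4σ). There is no curvature term; the Gaussian stage is the smoothness
mechanism, as the method family's name says. The signed pressure force is

    spf(I) = (I − (c₁ + c₂)/2) / max|I − (c₁ + c₂)/2|      (conventional)
    spf(I) = (I − (c₁ + C)/2)  / max|I − (c₁ + C)/2|       (OCT variant)

with c₁, c₂ the mean intensities inside/outside the contour under a binary
Heaviside (φ ≥ 0 counts as interior; since regularization forces φ to ±1
each iteration, a smoothed Heaviside would be indistinguishable). The OCT
variant replaces the drifting exterior mean with the fixed Stage-1 retinal
reference C.

### Balloon sign and confinement

The generic engine is sign-agnostic: with α > 0 the interior converges onto
{spf > 0} (bright targets), with α < 0 onto {spf < 0} (dark targets). Fluid
is hypo-reflective, so the OCT driver always contracts onto the dark side —
it uses an effective balloon of −|α| regardless of the sign passed in — and
pins the force outside the retina mask to be inward (spf clamped to the
expanding-bright value +1 under the negative balloon), so the contour cannot
leak into the background, which shares the fluid's darkness. The final mask
is intersected with the retina mask. A vanishing contour is reported as an
all-false mask with `converged = True`: a retina without fluid is a valid
clinical outcome, not an error.

### Initialization and convergence

The fluid contour is seeded at retina pixels darker than (c_dark + C)/2,
where c_dark is the darker K-means center; if none qualify, a single-pixel
seed at the darkest retina pixel (first in row-major order) is used, which
either grows into a missed pocket or is expelled, signalling "no fluid".

Convergence is relative interior-area stability: the run stops once
|ΔA|/max(A, 1) ≤ `conv_tol` for `conv_window` consecutive iterations (the
comparison is ≤ so that a tolerance of exactly 0 accepts a perfectly
stationary contour). Area is measured on the sign map of the evolved field,
and the loop exits immediately after that binarization, so the reported mask
is literally {φ > 0} at termination and always matches the last area-trace
entry; the Gaussian stage only conditions the next iteration's gradient.
Measuring the mask *after* smoothing would shift the contour by up to a
pixel at high-curvature boundaries and make exact recovery of a piecewise-
constant target impossible.

## Parameters

| parameter | default | units | role |
|---|---|---|---|
| α | 20 | – | balloon force magnitude; sign selects bright/dark target in the generic engine |
| dt | 1 | iterations⁻¹ | Euler step; dt·α sets the per-step push |
| σ | 1.0 | px | Gaussian regularization width (truncated at 4σ) |
| max_iter | 2000 | – | iteration cap |
| conv_tol | 10⁻³ | – | relative area-change tolerance |
| conv_window | 5 | – | consecutive stable iterations required |
| K-means tol | 10⁻⁶ | intensity | center-shift stopping threshold |

These are conventional settings for this level-set family; every one is a
configuration knob of the CLI and of `EvolutionParams`. Because the
binarization resets φ to ±1 each iteration, a pixel flips only when a single
step's increment exceeds 1, i.e. dt·α·|spf|·|∇φ| > 1; dt·α ≈ 20 makes
clearly-classified pixels flip in one step while near-midpoint pixels
(|spf| ≈ 0) stay put, which is what terminates the evolution at a fixed
point in practice.

## Synthetic phantoms

`phantom.generate` renders: dark background (μ_bg = 0.10), one parabolically
curved bright band (μ_band = 0.75, thickness 28–40 px in the default suite),
zero or more dark elliptical pockets strictly inside the band
(μ_fluid = 0.12), multiplicative gamma speckle with mean 1 (shape k = 30,
i.e. ≈ 18 % intensity CV — the standard multiplicative model for coherent-
imaging speckle; mean-1 scaling keeps the μ parameters interpretable as
class means), then Gaussian blur (σ = 1 px) and clipping to [0, 1]. Ground
truth comes from the pre-noise geometry, which makes the evaluation
reference unambiguous. `default_suite(n, seed)` randomizes band position,
curvature (±2–14 px of sag), thickness and 0–3 pockets per scan, with
sub-seeds spawned deterministically from the suite seed.

What the phantom does **not** model: retinal layering, vessel shadowing,
motion artifacts, subretinal vs. intraretinal fluid distinction, low-
contrast scans, and 3-D context. Passing tests therefore demonstrate
correctness of the algorithm on images with the stated statistical structure
(hyper-reflective band, hypo-reflective pockets, multiplicative speckle),
not clinical-grade performance; scans with very weak band/background
contrast or speckle heavy enough to bury the fluid signal are outside the
method's stated operating range.

## Numerical choices and degenerate inputs

- Intensity normalization divides by the container type's maximum (255 or
  65535) rather than min-max stretching: raw intensity order is preserved
  and no contrast-enhancement stage is invented.
- |∇φ| uses central differences in the interior and one-sided differences at
  borders; images smaller than 8×8 are rejected (no room for the stencil).
- spf normalization returns an identically-zero field when the numerator
  vanishes everywhere (constant image at the decision midpoint); otherwise
  max|spf| is exactly 1.
- K-means ties (a value equidistant from two centers) go to the lower-index
  (darker) center; an image with fewer distinct intensities than K is
  rejected as degenerate rather than silently returning duplicate centers.
- Metrics are computed over the full grid, not restricted to the retina; a
  zero denominator makes only that metric undefined (serialized as null),
  except Dice of two empty masks, which is an error the caller must handle.
- Non-finite φ values abort the run naming dt·α as the likely cause.

## Suite sizes

The bundled evaluation suite is 20 phantoms of 128×192 px; with the default
parameters the whole suite (both engines) runs in about a second on one CPU,
and the per-scan iteration counts are single-digit, so the suite size is set
by statistical convenience (a stable median over mixed geometries, including
fluid-free scans) rather than cost.

## Known limitations

- The iteration-economy comparison between the fixed-reference and
  conventional engines is directional; its margin depends on the phantom
  geometry distribution and on `conv_window`, and on some suite seeds the
  two medians tie.
- The conventional engine raises when a single-pixel seed collapses (empty
  interior); the OCT driver treats the same event as a valid "no fluid"
  outcome. Comparisons between the two count the conventional engine's
  iterations up to collapse.
- Stage 1 is the final retina segmentation; Stage 2 refines only the fluid
  region. The pipeline does not re-segment the retinal boundary with the
  level set.
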