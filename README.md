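# octdme

Segmentation of diabetic macular edema (DME) fluid in retinal OCT B-scans.

DME — fluid accumulating in the macula when the blood–retinal barrier breaks
down — appears on spectral-domain OCT as dark (hypo-reflective) pockets inside
the bright retinal band. Delineating those pockets by hand is slow and
subjective; `octdme` implements a fast, training-free two-stage pipeline aimed
at screening settings:

1. **Stage 1 — retina extraction.** K-means intensity clustering with K = 2
   splits the B-scan into retina (ROI) and background. The retina mask is the
   largest 8-connected bright component with enclosed holes filled (so fluid
   pockets stay inside it), and its mean intensity *C* becomes a fixed
   reference for Stage 2.
2. **Stage 2 — fluid delineation.** A selective-binary, Gaussian-regularized
   level set evolves a contour φ by a pure balloon force,

   ∂φ/∂t = α · spf(I) · |∇φ|,   spf(I) = (I − (c₁ + C)/2) / max|I − (c₁ + C)/2|,

   where c₁ is the mean intensity inside the evolving contour, recomputed each
   iteration. The conventional member of this level-set family uses the mean
   *outside* the contour, c₂, in place of C; anchoring the reference to the
   Stage-1 retinal intensity keeps the decision midpoint (c₁ + C)/2 inside the
   tissue/fluid contrast instead of letting the dark background drag it down,
   which confines the contour to intraretinal structures and shortens the
   evolution. After each Euler step φ is reset to its ±1 sign map and smoothed
   with a Gaussian — the regularization that replaces classical
   re-initialization. Convergence is declared when the interior pixel count is
   stable (relative change ≤ `conv_tol` for `conv_window` consecutive
   iterations).

Because clinical OCT data cannot ship with the package, a seeded phantom
generator produces synthetic B-scans — curved hyper-reflective band, dark
elliptical fluid pockets, multiplicative gamma speckle, optional blur — with
exact ground-truth masks, and a metrics module scores predictions (Dice,
precision, sensitivity, specificity; Dice > 0.70 is conventionally "excellent
agreement").

## Worked example

```python
import json
from octdme import (EvolutionParams, default_suite, extract_roi,
                    kmeans_intensity, report, run_sbgfrls_oct)

sample = default_suite(20, seed=0)[3]          # a speckled B-scan with fluid
model = kmeans_intensity(sample.image)         # Stage 1: K=2 intensity clustering
roi = extract_roi(sample.image, model)
result = run_sbgfrls_oct(sample.image, roi, EvolutionParams())

print(f"K-means centers: {model.centers.round(3)}")
print(f"retina reference C = {roi.C:.3f}, retina area = {roi.mask.sum()} px")
print(f"level set: {result.iterations} iterations, converged = {result.converged}")
print(f"fluid area = {result.mask.sum()} px")
print(json.dumps(report(result.mask, sample.dme_truth), indent=2))
```

prints

```
K-means centers: [0.107 0.732]
retina reference C = 0.705, retina area = 6720 px
level set: 6 iterations, converged = True
fluid area = 332 px
{
  "dice": 0.9984917043740573,
  "precision": 0.9969879518072289,
  "sensitivity": 1.0,
  "specificity": 0.9999587543823468,
  "tp": 331,
  "fp": 1,
  "tn": 24244,
  "fn": 0
}
```

The two cluster centers are the background/fluid (0.107) and retinal-band
(0.732) intensities; C is the mean intensity of the extracted retina. The
contour settles in 6 iterations and recovers the 331-pixel fluid pocket with
one false-positive pixel (Dice 0.998 against the phantom's ground truth).

## Command line

```sh
octdme phantom --n 5 --seed 0 --outdir scans/      # synthetic B-scans + truth
octdme segment scans/phantom_001.png --outdir out/ # masks, overlay, JSON report
octdme evaluate out/phantom_001.dme.png scans/phantom_001.dme.png
```

`segment` writes `<stem>.roi.png`, `<stem>.dme.png`, an overlay PNG (retina
boundary red, fluid boundary green) and a JSON run report containing the full
configuration and per-iteration area trace. Exit codes: 0 success, 1
usage/configuration error, 2 data/computation error.

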