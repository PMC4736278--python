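# atflseg

Segmentation of the **anterior talofibular ligament (ATFL)** — the ankle
ligament most prone to sprain injury — from 2D B-mode ultrasound images.

Ultrasound is the portable, non-ionizing modality of choice for ATFL
assessment, but the ligament is hard to delineate computationally: its mean
intensity barely exceeds the surrounding soft tissue, its speckle texture
matches its surroundings, and contrast drifts across the field of view.
`atflseg` implements a five-stage pipeline that addresses exactly these
challenges, together with synthetic speckle phantoms (with known truth
masks) and a complete validation-metric suite, so every stage is testable
without clinical data.

## The pipeline

1. **ROI crop** — a tight expert-style rectangle around the ligament.
2. **Adaptive histogram equalization** — each pixel is remapped by the
   cumulative histogram of its window, `v ↦ round((L−1)·CDF_w(v))`; the
   default window is the whole ROI (global equalization).
3. **PSO multilevel thresholding** — a particle swarm
   (`v ← w·v + c₁r₁(p−x) + c₂r₂(g−x)`, `x ← x + v`) maximizes the
   multilevel Otsu criterion `Σ_c ω_c (μ_c − μ)²` over K=2 thresholds; the
   image is then quantized to its class means ("optimized image").
4. **Chan–Vese level set** — the boundary is the zero contour of φ
   minimizing

   ```
   E(c₁,c₂,φ) = ∫(I−c₁)²H(φ) + ∫(I−c₂)²(1−H(φ)) + μ∫δ(φ)|∇φ|
   ```

   with the smooth Heaviside `H_ε(v) = ½(1 + (2/π)·arctan(v/ε))`, evolved by
   `φ ← φ + dt·δ_ε(φ)·[μ·κ(φ) − (I−c₁)² + (I−c₂)²]` for up to 800
   iterations. No edge detector is involved — the contour locks onto region
   statistics, which is what works on speckled, low-contrast tissue.
5. **Morphological smoothing** — closing with a disk of radius 10 px, hole
   filling, and largest-component selection.

Validation metrics: sensitivity, specificity, accuracy, Jaccard overlap,
directed and symmetric Hausdorff distance, segmented area, pairwise
inter-rater TPR, and mean/SD/CV cohort summaries.

## Worked example

Segment a torn-ligament phantom and score it against its truth mask:

```python
import numpy as np
from atflseg import (PhantomSpec, PipelineConfig, ROISpec,
                     generate_phantom, run_pipeline, crop_roi)

img, truth = generate_phantom(PhantomSpec(injury="tear", seed=4))
roi = ROISpec(104, 0, 72, 256)                   # tight band-centred crop
cfg = PipelineConfig(roi=roi, seed=0)
res = run_pipeline(img, cfg,
                   truth=crop_roi(truth.astype(np.uint8), roi).astype(bool))
m = res.metrics
print(f"thresholds : {np.floor(res.thresholds).astype(int)}")
print(f"cv stopped : iteration {res.state.iteration} "
      f"(c1={res.state.c1:.1f}, c2={res.state.c2:.1f})")
print(f"area       : {m.area_pred} px (truth {m.area_truth} px)")
print(f"sensitivity: {m.sensitivity:.3f}  specificity: {m.specificity:.3f}  "
      f"accuracy: {m.accuracy:.3f}")
print(f"jaccard    : {m.jaccard:.3f}  hausdorff: {m.hausdorff:.2f} px")
```

Output:

```
thresholds : [ 80 169]
cv stopped : iteration 420 (c1=204.0, c2=84.7)
area       : 7824 px (truth 6827 px)
sensitivity: 0.989  specificity: 0.908  accuracy: 0.938
jaccard    : 0.855  hausdorff: 20.02 px
```

The PSO placed its upper threshold inside the band's equalized intensity
range (169 of 255), the level set stopped after 420 of the allowed 800
iterations with well-separated region means (204 vs 85), and the recovered
region overlaps the truth band at Jaccard 0.855 despite the simulated tear
and speckle.

The same pipeline is available from the shell:

```sh
atflseg phantom cohort/ --n-per-group 5 --seed 0     # synthetic cohort
atflseg batch cohort/ --manifest cohort/manifest.csv --roi 104,0,72,256 --out report/
atflseg segment scan.png --roi 104,0,72,256 --out out/      # one image
atflseg evaluate --pred out/mask.png --truth truth.png
```

`batch` writes one metrics row per image plus a per-group mean/SD/CV
summary table.

## Limitations

The phantoms emulate the stated imaging challenges (low contrast,
homogeneous texture, speckle, lateral gain drift) but not beam physics
(anisotropy, attenuation, shadowing); see `docs/methods.md` for the model,
parameter choices, and known limitations.
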