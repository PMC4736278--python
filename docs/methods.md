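# Methods

This note documents the models, parameter choices and numerical decisions
behind `atflseg`, in the spirit of a methods appendix: what is computed,
why the defaults are what they are, and what the synthetic experiments do
and do not demonstrate.

## Problem setting

The anterior talofibular ligament appears in B-mode ultrasound as a thin,
gently curved hyperechoic band whose mean intensity barely exceeds the
surrounding soft tissue. Three image properties make automatic delineation
hard: near-homogeneous intensity between ligament and surroundings,
near-identical speckle texture, and low, laterally drifting contrast. The
pipeline is built around region statistics rather than edges for exactly
this reason: gradient-based contours have nothing reliable to lock onto.

## Stage models

### Adaptive histogram equalization (`enhance`)

The local histogram of a pixel weights every pixel of its `w × w` window
by the uniform kernel `w⁻²`; windows truncated by the image border are
renormalized to unit mass (no padding intensities are invented). The
transfer is the standard equalization map `v ↦ round((L−1)·CDF_w(v))`,
with one guard: a window whose histogram occupies a single bin maps its
pixel to itself. Without the guard a constant region would be blown to
white by `CDF = 1`.

The **default window is the whole ROI**, i.e. global histogram
equalization — the configuration appropriate when the ROI is already a
tight crop of the structure of interest. The sliding-window mode (odd `w`)
is a direct `O(N·w²)` evaluation intended for ROI-sized inputs.

A consequence that shapes the whole pipeline: equalization is
rank-preserving, so any subsequent histogram-shape criterion effectively
partitions by *mass quantiles*. See "ROI choice" below.

### PSO multilevel thresholding (`pso`)

The objective is the multilevel Otsu criterion: the between-class variance
`Σ_c ω_c (μ_c − μ)²` of the K+1 classes induced by K thresholds (floored
to integers; a pixel of value v belongs to class c iff
`t_{c−1} < v ≤ t_c`). Empty classes contribute zero. The swarm uses the
canonical update with inertia `w = 0.729` and acceleration constants
`c₁ = c₂ = 1.49445` (the constriction-equivalent setting), 30 particles,
200 iterations, velocity clamped to `±(L−1)/2`, positions clipped and
re-sorted after every move, and duplicate components nudged up one level.
One seeded generator with a fixed draw order (iteration → particle →
dimension → r₁ then r₂) makes runs bit-reproducible. Personal and global
bests only ever improve, so the best-fitness trace is monotone by
construction; on 64-level problems with K ≤ 2 the swarm reproduces
exhaustive search (verified in the test suite).

The "optimized image" passed onward replaces each pixel by its class mean
— the piecewise-constant simplification that preserves exactly the region
statistics the Chan–Vese data terms integrate. `K = 2` by default: one
class for the bright band, two for the background's darker and lighter
halves.

### Chan–Vese level set (`chanvese`)

Energy: two quadratic region-fit terms plus a length penalty
`μ ∫ δ(φ)|∇φ|`, with the arctan-regularized Heaviside
(`ε = 1`). For fixed φ the optimal region constants are the H-weighted
means; φ then descends
`φ ← φ + dt·δ_ε(φ)·[μ·κ(φ) − (I−c₁)² + (I−c₂)²]` with `dt = 0.5` and
curvature κ by central differences (edge-replicated borders, `1e-8` guard
on the gradient magnitude). φ is never reinitialized; the `δ_ε` factor
keeps updates concentrated near the front.

Numerical decisions that required care:

* **Intensity scale.** Input is rescaled by 1/255 to [0,1] before
  evolution. On the raw 0–255 scale the squared data force is ~6.5·10⁴ at
  full contrast, which makes any `μ < 1` inert: speckle-bright satellite
  pixels then survive the evolution and the radius-10 closing later welds
  them into gross over-segmentation. On the unit scale `μ = 0.2` genuinely
  regularizes. Reported `c1`/`c2` are mapped back to input units.
* **Reported means.** The state reports the *hard* masked means (the
  `ε → 0` minimizers), not the smooth-H means: with the heavy-tailed
  arctan Heaviside the smooth means approach the true region levels only
  as `|φ| → ∞`, which plain gradient descent never reaches.
* **Polarity.** The functional is invariant under
  `(φ, c₁, c₂) → (−φ, c₂, c₁)`; the gauge is fixed by always reporting the
  *brighter* phase as the interior (the ligament is the hyperechoic
  structure). Without this convention roughly 1 run in 10 returns the
  complement mask.
* **Initialization.** `centered-circle` (signed distance to a circle of
  radius `min(h,w)/3`) suits compact central targets such as the disk
  phantom. For a band spanning the whole ROI — or a torn, two-component
  band — the circular front cannot reach the far pixels within the
  iteration budget under unit-scale forces, so the pipeline default is the
  `checkerboard` initialization, which places zero crossings everywhere.
  A balanced checkerboard starts with `c₁ ≈ c₂` (both phases average the
  same pixels), zeroing the data force; the implementation therefore uses
  a small pattern amplitude (0.1) and a 5-iteration warm-up in which the
  provisional means are the image extremes, which breaks the symmetry in
  the data's direction immediately.
* **Stopping.** Up to 800 iterations (the framework's iteration budget),
  stopping early once the per-iteration sign-change fraction stays below
  `tol = 10⁻⁴` for 20 consecutive iterations. The streak requirement
  exists because a slow front legitimately flips zero pixels on isolated
  iterations. On the speckled cohort all 25 default phantoms converge
  between ~300 and ~700 iterations; doubling the cap to 1600 changes the
  raw masks by at most 0.2% of ROI pixels (typically 0%). Note that the
  later closing can amplify a small raw-mask residue several-fold when a
  fringe satellite appears or disappears near the band.

### Morphology (`morpho`)

Closing = dilation then erosion with a disk structuring element (pixels
within Euclidean distance ≤ r; default radius 10 px), computed on a
radius-padded frame and restricted to the image domain, which keeps the
operation extensive and idempotent. Hole filling floods 4-connected
background from the border; component selection keeps the largest
8-connected foreground region (ties go to the earliest row-major pixel).
Chain order: close → fill → largest. One consequence worth knowing: when a
tear gap survives the level set, largest-component selection can drop the
smaller band fragment unless closing has bridged the gap first; with the
default tear geometry (gap ≈ 12 px between rounded cap ends after
rasterization) the radius-10 disk usually, but not always, bridges it.

### Metrics (`metrics`)

Pixel-level confusion counts feed sensitivity `TP/(TP+FN)`, specificity
`TN/(TN+FP)` and accuracy `(TP+TN)/total`. Overlap is Jaccard
`|A∩B|/|A∪B|`; boundary agreement is the Hausdorff distance between
foreground coordinate sets — the *directed* form `max_a min_b ‖a−b‖` and
the *symmetric* `max` of both directions, which is the reporting default
(segmentation validation convention). Area is the foreground count; the
inter-rater reliability measure is sensitivity applied pairwise between
two raters' masks (asymmetric by design). Cohort summaries use the sample
(n−1) standard deviation and `CV = sd/mean`. Any metric with a vanishing
denominator raises an explicit undefined-metric signal and is recorded as
a missing value, never silently zero.

## Synthetic phantoms (`phantom`)

Each phantom is a 256×256 scene: a band of half-width 14 px around a
near-horizontal cubic-spline centerline (the probe is aligned with the
ligament's long axis in clinical scanning), mean 135, over background 95 —
a ~17% Weber contrast, deliberately low. The scene is multiplied by a
±8% linear lateral gain ramp (drifting contrast), then by mean-1 gamma
speckle with `looks = 12` (fully developed speckle after the spatial
compounding typical of display-processed B-mode), then blurred with a
σ = 1.2 px Gaussian standing in for the point-spread function, and
quantized to 8 bits. The truth mask is the exact rasterized band
(distance-to-centerline ≤ half-width), available by construction.

Injury variants: `tear` removes a 40 px arc of centerline — more than
twice the half-width, so the truth mask splits into two components;
`thickened` scales thickness ×1.5 and length ×0.5. The length factor is
0.5 rather than a milder trim because the rasterized band carries round
end caps of area πt² each: with a milder trim the thickened area would
exceed the torn area and the clinically observed mean-area ordering
normal > tear > thickened would invert. Cohorts jitter the centerline rows
(±4 px), thickness (±0.5 px) and both tissue means (±5 levels) per
phantom, which leaves the expected area ordering intact with margin.

What the phantoms do **not** model: beam anisotropy, depth-dependent
attenuation, acoustic shadowing, refraction, and anatomical clutter
(bone surfaces, vessels). Passing the synthetic experiments therefore
demonstrates the pipeline's statistical behavior under speckle and low
contrast, not clinical-grade performance.

## ROI choice

The pipeline takes the ROI as explicit numeric input; the default used for
phantom work is rows 104–176, all columns — a tight horizontal strip in
which the band occupies 35–45% of pixels, emulating the tight expert-drawn
crop of clinical practice. This fraction is not cosmetic: because
equalization reduces Otsu to a mass-quantile splitter, the upper threshold
lands at roughly the top third of intensity mass, and the pipeline
recovers the band cleanly only when the band's share of the ROI is at or
above that quantile. Looser crops (band share ≲ 30%) push the upper
threshold into the background's bright speckle tail and degrade overlap
noticeably — the quantitative argument for tight ROI initialization.

## Experiment sizes

The cohort experiments use 25 phantoms split 12 normal / 8 tear /
5 thickened (the clinical group structure), 256×256 pixels, with the
level-set budget of 800 iterations; group-area comparisons use 5 phantoms
per group. A full cohort evaluation, including the doubled-cap stability
check, runs in about two minutes on one CPU.

## Known limitations

* The sliding-window equalization mode is a direct evaluation; it is not
  intended for full-frame images.
* The level set can leave a handful of speckle-bright satellite pixels
  near the band fringe; most dissolve under the length penalty, but
  marginal ones are metastable, and the closing stage can amplify their
  presence/absence into visible mask differences between runs with
  different iteration caps on ~1 cohort image in 25.
* Largest-component selection assumes one ligament region; for a torn
  ligament whose gap survives closing, it reports the larger fragment.
* Hausdorff distances are computed between full foreground point sets
  (not boundaries); for filled regions of similar size this matches the
  boundary-based value closely but is not identical.
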