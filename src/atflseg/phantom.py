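"""Synthetic ultrasound-like ligament phantoms with known truth masks.

The anterior talofibular ligament appears in B-mode ultrasound as a thin,
gently curved band whose mean intensity barely exceeds the surrounding soft
tissue, whose texture matches its surroundings, and whose contrast drifts
laterally with probe coupling.  The phantom reproduces exactly those
challenges: a piecewise-constant band/background scene with a small intensity
gap, multiplicative speckle (mean-1 gamma noise), a slow lateral gain ramp,
and Gaussian blur standing in for the point-spread function.  Because the
scene is rasterized from an analytic centerline, the ground-truth mask is
known exactly — which is what makes every downstream stage testable without
clinical data.

Injury variants mirror the clinical groups: ``normal`` (intact band),
``tear`` (a gap of ``tear_gap`` pixels along the band), and ``thickened``
(a shorter, fatter band, whose in-image area ends up the smallest of the
three groups — the ordering observed clinically).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage
from scipy.interpolate import CubicSpline

__all__ = ["PhantomSpec", "generate_phantom", "make_cohort", "write_cohort"]

GROUPS = ("normal", "tear", "thickened")

#: Default centerline control points as (row, col) fractions of the image.
#: Near-horizontal with gentle undulation: the ligament is scanned with the
#: probe aligned along its long axis, so in a tight ROI view the band runs
#: almost parallel to the image rows.
_DEFAULT_CENTERLINE_FRAC = (
    (0.52, 0.04),
    (0.49, 0.28),
    (0.50, 0.50),
    (0.53, 0.72),
    (0.56, 0.96),
)

#: Default analysis ROI for the 256x256 phantom: a tight horizontal strip
#: around the band, emulating the expert-drawn crop in which the ligament
#: occupies roughly a third of the pixels.
DEFAULT_ROI = (104, 0, 72, 256)

#: Thickened-ligament geometry relative to the normal band: fatter but
#: shorter, so its rasterized area sits below both normal and torn bands.
THICKENED_THICKNESS_FACTOR = 1.5
THICKENED_LENGTH_FACTOR = 0.5


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of one synthetic ligament image.

    ``band_thickness`` is the half-width of the band in pixels.
    ``speckle_looks`` is the number of looks of the multiplicative gamma
    speckle (variance 1/looks); ``None`` disables noise (the infinite-look
    limit).  ``contrast_drift`` is the peak fractional lateral gain ramp.
    """

    height: int = 256
    width: int = 256
    band_centerline: tuple[tuple[float, float], ...] | None = None
    band_thickness: float = 14.0
    band_mean: float = 135.0
    background_mean: float = 95.0
    speckle_looks: int | None = 12
    blur_sigma: float = 1.2
    contrast_drift: float = 0.08
    injury: str = "normal"
    tear_gap: float = 40.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.injury not in GROUPS:
            raise ValueError(f"injury must be one of {GROUPS}, got {self.injury!r}")
        if not (0 <= self.band_mean <= 255 and 0 <= self.background_mean <= 255):
            raise ValueError("band_mean and background_mean must lie in [0, 255]")
        if self.speckle_looks is not None and self.speckle_looks < 1:
            raise ValueError("speckle_looks must be >= 1 (or None to disable)")
        if self.blur_sigma < 0:
            raise ValueError("blur_sigma must be >= 0")
        if self.injury == "tear" and self.tear_gap < 1:
            raise ValueError("tear_gap must be >= 1 for injury='tear'")

    @property
    def contrast_gap(self) -> float:
        return self.band_mean - self.background_mean

    def centerline_points(self) -> np.ndarray:
        """Control points in absolute (row, col) pixel coordinates."""
        if self.band_centerline is not None:
            return np.asarray(self.band_centerline, dtype=np.float64)
        frac = np.asarray(_DEFAULT_CENTERLINE_FRAC)
        return frac * np.array([self.height, self.width])


def _sample_centerline(points: np.ndarray, step: float = 0.25) -> np.ndarray:
    """Densely sample a natural cubic spline through the control points,
    parameterized by cumulative chord length."""
    if len(points) < 2:
        raise ValueError("centerline needs at least two control points")
    chord = np.r_[0.0, np.cumsum(np.linalg.norm(np.diff(points, axis=0), axis=1))]
    spline = CubicSpline(chord, points, axis=0)
    s = np.arange(0.0, chord[-1] + step, step)
    return spline(s)


def _rasterize_band(
    shape: tuple[int, int], samples: np.ndarray, thickness: float
) -> np.ndarray:
    """Band mask = pixels within ``thickness`` of the sampled centerline
    (Euclidean distance transform of the rounded sample set)."""
    seed_grid = np.ones(shape, dtype=bool)
    rows = np.clip(np.rint(samples[:, 0]).astype(int), 0, shape[0] - 1)
    cols = np.clip(np.rint(samples[:, 1]).astype(int), 0, shape[1] - 1)
    seed_grid[rows, cols] = False
    dist = ndimage.distance_transform_edt(seed_grid)
    return dist <= thickness


def truth_mask(spec: PhantomSpec) -> np.ndarray:
    """Rasterize the injury-adjusted band as the ground-truth mask."""
    samples = _sample_centerline(spec.centerline_points())
    thickness = spec.band_thickness
    if spec.injury == "thickened":
        thickness *= THICKENED_THICKNESS_FACTOR
        n = len(samples)
        lo = int(n * (1 - THICKENED_LENGTH_FACTOR) / 2)
        samples = samples[lo : n - lo]
    elif spec.injury == "tear":
        # remove centerline samples within tear_gap/2 arc length of the middle
        arclen = np.r_[0.0, np.cumsum(np.linalg.norm(np.diff(samples, axis=0), axis=1))]
        mid = arclen[-1] / 2
        keep = np.abs(arclen - mid) > spec.tear_gap / 2
        samples = samples[keep]

    h, w = spec.height, spec.width
    if (
        samples[:, 0].min() < thickness
        or samples[:, 0].max() > h - 1 - thickness
        or samples[:, 1].min() < -0.5
        or samples[:, 1].max() > w - 0.5
    ):
        raise ValueError("band exceeds image bounds after thickening")
    return _rasterize_band((h, w), samples, thickness)


def generate_phantom(spec: PhantomSpec) -> tuple[np.ndarray, np.ndarray]:
    """Render one phantom; returns ``(image uint8, truth mask bool)``.

    The scene is band/background means, times a lateral gain ramp, times
    mean-1 gamma speckle, then Gaussian-blurred and clipped to 0–255.
    Identical specs (including seed) give bit-identical output.
    """
    mask = truth_mask(spec)
    scene = np.where(mask, spec.band_mean, spec.background_mean).astype(np.float64)

    if spec.contrast_drift:
        ramp = 1.0 + spec.contrast_drift * np.linspace(-1, 1, spec.width)
        scene *= ramp[None, :]

    rng = np.random.default_rng(spec.seed)
    if spec.speckle_looks is not None:
        looks = spec.speckle_looks
        scene *= rng.gamma(shape=looks, scale=1.0 / looks, size=scene.shape)
    if spec.blur_sigma > 0:
        scene = ndimage.gaussian_filter(scene, spec.blur_sigma)

    img = np.clip(np.rint(scene), 0, 255).astype(np.uint8)
    return img, mask


def make_cohort(
    n_per_group: int | dict[str, int],
    base_spec: PhantomSpec | None = None,
    seed: int = 0,
) -> list[tuple[np.ndarray, np.ndarray, str]]:
    """Generate a cohort of phantoms with jittered geometry per group.

    ``n_per_group`` is either one count applied to every group or a mapping
    ``{group: count}`` (e.g. the clinical 12/8/5 split).  Jitter perturbs the
    centerline control points (±4 px rows), thickness (±0.5 px) and tissue
    means (±5 levels) so cohort statistics are non-degenerate while the
    expected truth-area ordering normal > tear > thickened is preserved.
    """
    base = base_spec if base_spec is not None else PhantomSpec()
    if isinstance(n_per_group, int):
        if n_per_group < 1:
            raise ValueError("n_per_group must be >= 1")
        counts = {g: n_per_group for g in GROUPS}
    else:
        counts = dict(n_per_group)

    master = np.random.default_rng(seed)
    cohort: list[tuple[np.ndarray, np.ndarray, str]] = []
    for group in GROUPS:
        for _ in range(counts.get(group, 0)):
            pts = base.centerline_points().copy()
            pts[:, 0] += master.uniform(-4, 4, size=len(pts))
            spec = replace(
                base,
                band_centerline=tuple(map(tuple, pts)),
                band_thickness=base.band_thickness + master.uniform(-0.5, 0.5),
                band_mean=base.band_mean + master.uniform(-5, 5),
                background_mean=base.background_mean + master.uniform(-5, 5),
                injury=group,
                seed=int(master.integers(0, 2**31 - 1)),
            )
            img, mask = generate_phantom(spec)
            cohort.append((img, mask, group))
    return cohort


def write_cohort(
    out_dir,
    n_per_group: int | dict[str, int],
    base_spec: PhantomSpec | None = None,
    seed: int = 0,
):
    """Write a cohort to ``out_dir`` (images, truth masks, manifest CSV).

    Returns the manifest as a ``pandas.DataFrame`` with columns
    ``image, truth, group, truth_area``.
    """
    import os

    import pandas as pd

    from .imgio import save_image, save_mask

    os.makedirs(out_dir, exist_ok=True)
    rows = []
    for i, (img, mask, group) in enumerate(make_cohort(n_per_group, base_spec, seed)):
        img_name = f"phantom_{i:03d}_{group}.png"
        mask_name = f"phantom_{i:03d}_{group}_truth.png"
        save_image(img, os.path.join(out_dir, img_name))
        save_mask(mask, os.path.join(out_dir, mask_name))
        rows.append(
            {
                "image": img_name,
                "truth": mask_name,
                "group": group,
                "truth_area": int(mask.sum()),
            }
        )
    manifest = pd.DataFrame(rows)
    manifest.to_csv(os.path.join(out_dir, "manifest.csv"), index=False)
    return manifest
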