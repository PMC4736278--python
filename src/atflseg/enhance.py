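"""Contrast enhancement by (windowed) adaptive histogram equalization.

The local histogram of a pixel weights each window pixel by the uniform
rectangular kernel w^-2; windows truncated by the image border are
renormalized to unit mass.  The equalization transfer is the standard
round((L-1) * CDF(v)) mapping, with one guard: a window whose histogram has
a single occupied bin maps its pixel to itself (a flat region carries no
contrast to redistribute, and the plain transfer would blow a constant
image up to white).

The default window is the whole image — windowed equalization then reduces
to global histogram equalization — and a true sliding-window mode is kept
for locally varying contrast.  The sliding mode is a direct O(N * w^2)
evaluation; it is meant for ROI-sized inputs, not full scans.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["AHEConfig", "local_histogram", "equalize"]

FULL_WINDOW = "full"


@dataclass(frozen=True)
class AHEConfig:
    """``window``: odd width of the square kernel, or ``"full"``; ``levels``:
    number of gray levels (256 for 8-bit input)."""

    window: int | str = FULL_WINDOW
    levels: int = 256

    def __post_init__(self) -> None:
        if self.window != FULL_WINDOW:
            if not isinstance(self.window, int) or self.window < 1 or self.window % 2 == 0:
                raise ValueError("window must be an odd integer >= 1 or 'full'")
        if self.levels < 2:
            raise ValueError("levels must be >= 2")


def _window_values(img: np.ndarray, center: tuple[int, int], window: int) -> np.ndarray:
    r, c = center
    half = window // 2
    return img[
        max(r - half, 0) : r + half + 1, max(c - half, 0) : c + half + 1
    ].ravel()


def local_histogram(
    img: np.ndarray, center: tuple[int, int], cfg: AHEConfig = AHEConfig()
) -> np.ndarray:
    """Unit-mass histogram of the window centered on ``center``.

    Every in-window pixel carries the kernel weight w^-2; truncated border
    windows are renormalized so the bins always sum to 1.
    """
    img = np.asarray(img)
    r, c = center
    if not (0 <= r < img.shape[0] and 0 <= c < img.shape[1]):
        raise ValueError(f"center {center} outside image {img.shape}")
    if cfg.window == FULL_WINDOW:
        values = img.ravel()
    else:
        values = _window_values(img, center, cfg.window)
    hist = np.bincount(values, minlength=cfg.levels).astype(np.float64)
    return hist / hist.sum()


def _equalize_full(img: np.ndarray, levels: int) -> np.ndarray:
    hist = np.bincount(img.ravel(), minlength=levels).astype(np.float64)
    if np.count_nonzero(hist) == 1:
        return img.copy()
    cdf = np.cumsum(hist) / hist.sum()
    lut = np.rint((levels - 1) * cdf)
    return lut[img].astype(img.dtype)


def equalize(img: np.ndarray, cfg: AHEConfig = AHEConfig()) -> np.ndarray:
    """Histogram-equalize ``img``; global when ``cfg.window == "full"``.

    In sliding-window mode each pixel is remapped by the CDF of its own
    (truncated, renormalized) window, which adapts the transfer to local
    contrast at the cost of a direct per-pixel window scan.
    """
    img = np.asarray(img)
    if img.ndim != 2:
        raise ValueError("expected a 2D grayscale image")
    if cfg.window == FULL_WINDOW:
        return _equalize_full(img, cfg.levels)

    out = np.empty_like(img)
    for r in range(img.shape[0]):
        for c in range(img.shape[1]):
            values = _window_values(img, (r, c), cfg.window)
            v = img[r, c]
            if (values == values[0]).all():
                out[r, c] = v  # single occupied bin: identity
            else:
                cdf_v = np.count_nonzero(values <= v) / values.size
                out[r, c] = np.rint((cfg.levels - 1) * cdf_v)
    return out
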