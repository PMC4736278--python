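"""Grayscale image and binary-mask I/O, ROI cropping, and boundary overlays.

All images are 2D ``numpy.uint8`` arrays with intensities in 0–255, indexed
``(row, col)`` with a 0-based top-left origin.  Binary masks are 2D boolean
arrays of the same shape semantics and are stored on disk as {0, 255} PNGs.
"""

from __future__ import annotations

import os
from dataclasses import dataclass

import imageio.v3 as iio
import numpy as np

__all__ = [
    "ROISpec",
    "load_image",
    "save_image",
    "load_mask",
    "save_mask",
    "crop_roi",
    "mask_boundary",
    "overlay_boundary",
]

#: ITU-R BT.601 luma weights used to collapse color inputs to grayscale.
_LUMA = np.array([0.299, 0.587, 0.114])

_SUPPORTED_SUFFIXES = {".png", ".tif", ".tiff", ".bmp", ".jpg", ".jpeg"}


@dataclass(frozen=True)
class ROISpec:
    """Axis-aligned rectangle: half-open ``[row0, row0+height) x [col0, col0+width)``."""

    row0: int
    col0: int
    height: int
    width: int

    def __post_init__(self) -> None:
        if self.height < 1 or self.width < 1:
            raise ValueError("ROI height and width must be >= 1")
        if self.row0 < 0 or self.col0 < 0:
            raise ValueError("ROI origin must be non-negative")

    def validate_within(self, shape: tuple[int, int]) -> None:
        """Raise ``ValueError`` if the rectangle leaves the host image."""
        h, w = shape
        if self.row0 + self.height > h or self.col0 + self.width > w:
            raise ValueError(
                f"ROI {self} exceeds image bounds {h}x{w}; refusing to clamp"
            )

    @property
    def slices(self) -> tuple[slice, slice]:
        return (
            slice(self.row0, self.row0 + self.height),
            slice(self.col0, self.col0 + self.width),
        )


def _to_uint8_gray(arr: np.ndarray) -> np.ndarray:
    """Collapse channels with luma weights; rescale >8-bit data by min-max."""
    arr = np.asarray(arr)
    if arr.ndim == 3:
        if arr.shape[2] == 4:  # drop alpha
            arr = arr[:, :, :3]
        arr = arr.astype(np.float64) @ _LUMA
    elif arr.ndim != 2:
        raise ValueError(f"expected a 2D or 3D image array, got ndim={arr.ndim}")
    arr = arr.astype(np.float64)
    if arr.max() > 255:  # 16-bit input: linear min-max to the 8-bit range
        lo, hi = arr.min(), arr.max()
        arr = (arr - lo) / (hi - lo) * 255.0
    return np.clip(np.rint(arr), 0, 255).astype(np.uint8)


def load_image(path: str | os.PathLike) -> np.ndarray:
    """Read an image file as an 8-bit grayscale array.

    Color inputs are converted by BT.601 luma weighting; 16-bit inputs are
    linearly rescaled to 0–255.
    """
    path = os.fspath(path)
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    suffix = os.path.splitext(path)[1].lower()
    if suffix not in _SUPPORTED_SUFFIXES:
        raise ValueError(f"unsupported image format {suffix!r}: {path}")
    try:
        arr = iio.imread(path)
    except Exception as exc:  # pragma: no cover - backend specific
        raise ValueError(f"unreadable image file {path}: {exc}") from exc
    return _to_uint8_gray(arr)


def save_image(img: np.ndarray, path: str | os.PathLike) -> None:
    """Write a grayscale image; PNG/TIFF round-trip losslessly."""
    img = np.asarray(img)
    if img.dtype != np.uint8:
        img = np.clip(np.rint(np.asarray(img, dtype=np.float64)), 0, 255).astype(np.uint8)
    iio.imwrite(os.fspath(path), img)


def load_mask(path: str | os.PathLike) -> np.ndarray:
    """Read a binary mask stored as a {0,255} (or any thresholdable) image."""
    return load_image(path) > 127


def save_mask(mask: np.ndarray, path: str | os.PathLike) -> None:
    """Write a boolean mask as a {0,255} PNG."""
    mask = np.asarray(mask).astype(bool)
    iio.imwrite(os.fspath(path), (mask.astype(np.uint8)) * 255)


def crop_roi(img: np.ndarray, roi: ROISpec) -> np.ndarray:
    """Extract the ROI rectangle; out-of-bounds ROIs raise rather than clamp."""
    img = np.asarray(img)
    roi.validate_within(img.shape[:2])
    return img[roi.slices].copy()


def mask_boundary(mask: np.ndarray) -> np.ndarray:
    """Foreground pixels 4-adjacent to background (the image border counts
    as background, so foreground touching the border is boundary)."""
    from scipy import ndimage

    mask = np.asarray(mask).astype(bool)
    interior = ndimage.binary_erosion(
        mask, structure=ndimage.generate_binary_structure(2, 1), border_value=0
    )
    return mask & ~interior


def overlay_boundary(
    img: np.ndarray, mask: np.ndarray, color: tuple[int, int, int] = (255, 64, 64)
) -> np.ndarray:
    """Paint the mask boundary in ``color`` over the grayscale image (RGB out)."""
    img = np.asarray(img)
    mask = np.asarray(mask).astype(bool)
    if img.shape != mask.shape:
        raise ValueError(f"image shape {img.shape} != mask shape {mask.shape}")
    rgb = np.repeat(img[:, :, None], 3, axis=2).astype(np.uint8)
    rgb[mask_boundary(mask)] = np.asarray(color, dtype=np.uint8)
    return rgb
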