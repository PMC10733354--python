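"""Image and mask I/O, intensity normalization, and denoising filters.

Rasters are plain 2-D :class:`numpy.ndarray` objects throughout the package:
gray images as integer arrays with values in ``[0, levels - 1]`` (256 gray
levels by default), binary masks as boolean arrays of the same shape.
Coordinates are 0-based ``(row, col)``, row-major.
"""

from __future__ import annotations

import os

import numpy as np
from PIL import Image
from scipy import ndimage

__all__ = [
    "load_image",
    "save_image",
    "load_mask",
    "save_mask",
    "load_nifti_slice",
    "normalize",
    "denoise",
    "validate_gray_image",
    "validate_mask",
]

#: ITU-R BT.601 luminance weights for RGB -> gray conversion.
_LUMA = np.array([0.299, 0.587, 0.114])


def validate_gray_image(img: np.ndarray, levels: int = 256) -> np.ndarray:
    """Check that *img* is a valid 2-D gray raster; return it as an array."""
    arr = np.asarray(img)
    if arr.ndim != 2:
        raise ValueError(f"expected a 2-D raster, got shape {arr.shape}")
    if arr.size == 0:
        raise ValueError("image has zero size")
    if arr.min() < 0 or arr.max() > levels - 1:
        raise ValueError(f"pixel values outside [0, {levels - 1}]")
    return arr


def validate_mask(mask: np.ndarray, shape: tuple[int, int] | None = None) -> np.ndarray:
    """Check that *mask* is a 2-D {0,1} raster; return it as boolean."""
    arr = np.asarray(mask)
    if arr.ndim != 2 or arr.size == 0:
        raise ValueError(f"expected a non-empty 2-D mask, got shape {arr.shape}")
    if arr.dtype != bool and not np.isin(arr, (0, 1)).all():
        raise ValueError("mask values must be 0 or 1")
    if shape is not None and arr.shape != tuple(shape):
        raise ValueError(f"mask shape {arr.shape} does not match image shape {shape}")
    return arr.astype(bool)


def normalize(arr: np.ndarray, levels: int = 256) -> np.ndarray:
    """Min-max rescale an arbitrary raster to integer gray levels [0, levels-1].

    A constant raster (zero dynamic range) maps to all zeros.
    """
    arr = np.asarray(arr, dtype=float)
    lo, hi = float(arr.min()), float(arr.max())
    if hi == lo:
        return np.zeros(arr.shape, dtype=np.int64)
    scaled = np.rint((levels - 1) * (arr - lo) / (hi - lo))
    return scaled.astype(np.int64)


def load_image(path: str | os.PathLike, levels: int = 256) -> np.ndarray:
    """Load a PNG/TIFF image as a gray raster rescaled to ``[0, levels-1]``.

    RGB input is converted to luminance first; 16-bit input is supported.
    Already-in-range 8-bit input with ``levels=256`` passes through unchanged
    up to the min-max rescale (an image spanning [0, 255] is unaffected).
    """
    with Image.open(path) as im:
        arr = np.asarray(im)
    if arr.size == 0:
        raise ValueError(f"zero-sized image: {path}")
    if arr.ndim == 3:  # RGB or RGBA: luminance conversion
        arr = arr[..., :3].astype(float) @ _LUMA
    return normalize(arr, levels=levels)


def save_image(img: np.ndarray, path: str | os.PathLike) -> None:
    """Write an 8-bit gray raster as PNG/TIFF (values must fit in [0, 255])."""
    arr = validate_gray_image(img, levels=256).astype(np.uint8)
    Image.fromarray(arr, mode="L").save(path)


def save_mask(mask: np.ndarray, path: str | os.PathLike) -> None:
    """Write a binary mask as a 1-channel PNG with values {0, 255}."""
    arr = validate_mask(mask)
    Image.fromarray((arr.astype(np.uint8)) * 255, mode="L").save(path)


def load_mask(path: str | os.PathLike) -> np.ndarray:
    """Read a {0,255} (or {0,1}) PNG mask back as a boolean raster."""
    with Image.open(path) as im:
        arr = np.asarray(im.convert("L"))
    return arr > 0


def load_nifti_slice(path: str | os.PathLike, index: int, axis: int = 2,
                     levels: int = 256) -> np.ndarray:
    """Extract one slice from a NIfTI volume as a normalized gray raster.

    Requires the optional ``nibabel`` dependency.
    """
    import nibabel as nib

    vol = np.asanyarray(nib.load(os.fspath(path)).dataobj)
    if vol.ndim != 3:
        raise ValueError(f"expected a 3-D volume, got shape {vol.shape}")
    sl = np.take(vol, index, axis=axis)
    return normalize(sl, levels=levels)


def denoise(img: np.ndarray, method: str = "median", window: int = 3,
            levels: int = 256) -> np.ndarray:
    """Median or average (mean) filtering with edge replication at borders.

    The average filter rounds back to the nearest integer gray level so the
    output stays a valid gray raster.
    """
    arr = validate_gray_image(img, levels=levels)
    if window % 2 == 0 or window < 1:
        raise ValueError(f"window must be odd and >= 1, got {window}")
    if method == "median":
        out = ndimage.median_filter(arr, size=window, mode="nearest")
    elif method == "average":
        sm = ndimage.uniform_filter(arr.astype(float), size=window, mode="nearest")
        out = np.rint(sm).astype(np.int64)
    else:
        raise ValueError(f"unknown denoise method: {method!r}")
    return out
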