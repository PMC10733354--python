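"""Morphological cleanup and the pixel-count tumor decision.

The cleaned mask is reduced to its largest 8-connected component — the tumor
candidate — and the presence decision follows the pixel-count rule: zero
pixels means no tumor region.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage import morphology

from .imgio import validate_mask


def _remove_small(mask: np.ndarray, min_area: int) -> np.ndarray:
    labels, n = ndimage.label(mask, structure=_STRUCT8)
    if n == 0:
        return mask
    sizes = ndimage.sum_labels(mask, labels, index=np.arange(1, n + 1))
    keep = np.flatnonzero(sizes >= min_area) + 1
    return np.isin(labels, keep)

__all__ = ["TumorRegion", "morphological_clean", "extract_tumor"]

_STRUCT8 = np.ones((3, 3), dtype=bool)  # 8-connectivity


@dataclass(frozen=True)
class TumorRegion:
    mask: np.ndarray          # boolean raster of the retained component
    pixel_count: int
    bbox: tuple[int, int, int, int] | None  # (row0, col0, row1, col1), half-open
    centroid: tuple[float, float] | None
    present: bool


def morphological_clean(mask: np.ndarray, open_radius: int = 1,
                        min_area: int = 16) -> np.ndarray:
    """Binary opening with a disk element, then small-component removal."""
    m = validate_mask(mask)
    if open_radius < 0:
        raise ValueError("open_radius must be >= 0")
    if open_radius > 0:
        m = ndimage.binary_opening(m, structure=morphology.disk(open_radius))
    if min_area > 0:
        m = _remove_small(m, min_area)
    return m


def extract_tumor(mask: np.ndarray) -> TumorRegion:
    """Largest 8-connected component with its size, bounding box and centroid."""
    m = validate_mask(mask)
    labels, n = ndimage.label(m, structure=_STRUCT8)
    if n == 0:
        return TumorRegion(mask=np.zeros_like(m), pixel_count=0, bbox=None,
                           centroid=None, present=False)
    sizes = ndimage.sum_labels(m, labels, index=np.arange(1, n + 1))
    best = int(np.argmax(sizes)) + 1
    comp = labels == best
    rows, cols = np.nonzero(comp)
    bbox = (int(rows.min()), int(cols.min()), int(rows.max()) + 1, int(cols.max()) + 1)
    centroid = (float(rows.mean()), float(cols.mean()))
    return TumorRegion(mask=comp, pixel_count=int(comp.sum()), bbox=bbox,
                       centroid=centroid, present=True)
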