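"""Gray-level co-occurrence matrices and statistical texture features.

The feature set follows the standard Haralick definitions for the GLCM
statistics (contrast, correlation, energy, inverse difference moment,
entropy) and ordinary moment definitions for the first-order statistics
computed on the segmented region (mean, standard deviation, variance, RMS,
histogram entropy, skewness, kurtosis, smoothness).  Entropies are in bits.

Smoothness is ``1 - 1/(1 + sigma_n^2)`` with ``sigma_n`` the standard
deviation of intensities rescaled to [0, 1]; it is 0 for a constant region
and grows toward 1 with contrast.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .imgio import validate_gray_image, validate_mask
from .wavelet import dwft2, get_wavelet, multilevel_dwt, subband_energy_features

__all__ = [
    "GLCM",
    "GLCMConfig",
    "WaveletFeatureConfig",
    "FOUR_DIRECTIONS",
    "compute_glcm",
    "glcm_features",
    "first_order_features",
    "extract_feature_vector",
    "feature_names",
]

#: Unit displacements at 0, 45, 90 and 135 degrees as (drow, dcol) offsets.
FOUR_DIRECTIONS = ((0, 1), (-1, 1), (-1, 0), (-1, -1))


@dataclass(frozen=True)
class GLCM:
    """Co-occurrence probabilities of quantized gray-level pairs."""

    p: np.ndarray          # Ng x Ng probabilities, sums to 1
    ng: int                # quantized level count
    offset: tuple[int, int]
    symmetric: bool
    counts: np.ndarray     # raw pair counts before normalization


@dataclass(frozen=True)
class GLCMConfig:
    ng: int = 32
    distance: int = 1
    symmetric: bool = True


@dataclass(frozen=True)
class WaveletFeatureConfig:
    name: str = "haar"
    levels: int = 3
    frame: bool = False  # True: undecimated (shift-invariant) energies


def _quantize(img: np.ndarray, ng: int, levels: int) -> np.ndarray:
    """Uniform binning of [0, levels-1] into ng levels."""
    return np.minimum((np.asarray(img, dtype=float) * ng / levels).astype(np.int64),
                      ng - 1)


def compute_glcm(img: np.ndarray, ng: int = 32, offset: tuple[int, int] = (0, 1),
                 symmetric: bool = True, levels: int = 256) -> GLCM:
    """Count co-occurring quantized gray-level pairs at a fixed displacement.

    A pair is the ordered (reference, neighbor) couple with the neighbor at
    ``offset = (drow, dcol)`` from the reference; pairs crossing the image
    border are dropped.  With *symmetric*, the transpose counts are added.
    """
    arr = validate_gray_image(img, levels=levels)
    if ng < 2:
        raise ValueError("ng must be >= 2")
    dr, dc = offset
    if dr == dc == 0 or abs(dr) >= arr.shape[0] or abs(dc) >= arr.shape[1]:
        raise ValueError(f"offset {offset} invalid for image shape {arr.shape}")
    q = _quantize(arr, ng, levels)
    rows = slice(max(0, -dr), min(arr.shape[0], arr.shape[0] - dr))
    cols = slice(max(0, -dc), min(arr.shape[1], arr.shape[1] - dc))
    ref = q[rows, cols]
    nbr = q[rows.start + dr: rows.stop + dr, cols.start + dc: cols.stop + dc]
    counts = np.zeros((ng, ng), dtype=np.int64)
    np.add.at(counts, (ref.ravel(), nbr.ravel()), 1)
    if symmetric:
        counts = counts + counts.T
    total = counts.sum()
    if total == 0:
        raise ValueError("no valid pixel pairs for this offset")
    return GLCM(p=counts / total, ng=ng, offset=(dr, dc), symmetric=symmetric,
                counts=counts)


def glcm_features(glcm: GLCM) -> dict[str, float]:
    """Haralick statistics of a normalized co-occurrence matrix."""
    p = np.asarray(glcm.p, dtype=float)
    if abs(p.sum() - 1.0) > 1e-9 or (p < 0).any():
        raise ValueError("GLCM is not a normalized probability matrix")
    i, j = np.indices(p.shape)
    contrast = float(((i - j) ** 2 * p).sum())
    energy = float((p**2).sum())
    idm = float((p / (1.0 + (i - j) ** 2)).sum())
    mu_i = float((i * p).sum())
    mu_j = float((j * p).sum())
    var_i = float(((i - mu_i) ** 2 * p).sum())
    var_j = float(((j - mu_j) ** 2 * p).sum())
    denom = np.sqrt(var_i * var_j)
    correlation = float(((i * j * p).sum() - mu_i * mu_j) / denom) if denom > 0 else 0.0
    nz = p[p > 0]
    entropy = float(-(nz * np.log2(nz)).sum())
    return {"contrast": contrast, "correlation": correlation, "energy": energy,
            "idm": idm, "glcm_entropy": entropy}


def first_order_features(img: np.ndarray, mask: np.ndarray | None = None,
                         levels: int = 256) -> dict[str, float]:
    """First-order statistics of the (masked) intensity distribution."""
    arr = validate_gray_image(img, levels=levels)
    if mask is not None:
        m = validate_mask(mask, shape=arr.shape)
        region = arr[m].astype(float)
    else:
        region = arr.ravel().astype(float)
    if region.size == 0:
        raise ValueError("empty region")
    mean = float(region.mean())
    var = float(region.var())  # population variance
    std = float(np.sqrt(var))
    rms = float(np.sqrt(np.mean(region**2)))
    counts = np.bincount(region.astype(np.int64), minlength=levels)
    probs = counts[counts > 0] / region.size
    entropy = float(-(probs * np.log2(probs)).sum())
    if std > 0:
        centered = region - mean
        skewness = float(np.mean(centered**3) / std**3)
        kurtosis = float(np.mean(centered**4) / std**4 - 3.0)  # excess
    else:
        skewness = kurtosis = 0.0
    sigma_n = std / (levels - 1)
    smoothness = 1.0 - 1.0 / (1.0 + sigma_n**2)
    return {"mean": mean, "standard_deviation": std, "variance": var, "rms": rms,
            "entropy": entropy, "skewness": skewness, "kurtosis": kurtosis,
            "smoothness": smoothness}


_FIRST_ORDER = ("mean", "standard_deviation", "variance", "rms", "entropy",
                "skewness", "kurtosis", "smoothness")
_GLCM_FEATS = ("contrast", "correlation", "energy", "idm", "glcm_entropy")


def feature_names(wavelet_cfg: WaveletFeatureConfig | None = None) -> list[str]:
    """Deterministic ordering of the full feature vector."""
    cfg = wavelet_cfg or WaveletFeatureConfig()
    names = list(_FIRST_ORDER) + list(_GLCM_FEATS)
    names.append(f"wav_energy_A{cfg.levels}")
    for lev in range(1, cfg.levels + 1):
        names += [f"wav_energy_{b}{lev}" for b in ("H", "V", "D")]
    return names


def extract_feature_vector(img: np.ndarray, mask: np.ndarray | None = None,
                           glcm_cfg: GLCMConfig | None = None,
                           wavelet_cfg: WaveletFeatureConfig | None = None,
                           levels: int = 256) -> dict[str, float]:
    """The full named texture feature vector of one image.

    First-order statistics are computed on the masked region (whole image if
    *mask* is None), GLCM statistics are averaged over the four unit
    directions, and wavelet sub-band energies are computed on the whole
    image (decimated by default, undecimated when ``wavelet_cfg.frame``).
    """
    glcm_cfg = glcm_cfg or GLCMConfig()
    wavelet_cfg = wavelet_cfg or WaveletFeatureConfig()
    feats = first_order_features(img, mask, levels=levels)

    acc = {k: 0.0 for k in _GLCM_FEATS}
    for dr, dc in FOUR_DIRECTIONS:
        g = compute_glcm(img, ng=glcm_cfg.ng,
                         offset=(dr * glcm_cfg.distance, dc * glcm_cfg.distance),
                         symmetric=glcm_cfg.symmetric, levels=levels)
        for k, v in glcm_features(g).items():
            acc[k] += v / len(FOUR_DIRECTIONS)
    feats.update(acc)

    fp = get_wavelet(wavelet_cfg.name)
    if wavelet_cfg.frame:
        bands = dwft2(img, fp, level=wavelet_cfg.levels)
    else:
        bands = multilevel_dwt(img, fp, level=wavelet_cfg.levels)
    feats.update(subband_energy_features(bands))
    return feats
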