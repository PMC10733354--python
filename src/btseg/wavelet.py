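"""2-D discrete wavelet transform (DWT), its undecimated frame variant
(DWFT), and sub-band energy features.

The transform is separable and uses orthonormal analysis filters with
periodic (circular) boundary extension and even-index dyadic downsampling.
With these conventions the decimated transform of an even-sized raster is an
orthogonal map: perfect reconstruction and energy conservation hold exactly
(to round-off), and the undecimated variant is exactly equivariant under
circular shifts — the property that makes its sub-band energies
translation-invariant texture features.

One decomposition level yields four sub-bands: the approximation A (low-pass
in both axes) and the detail rasters H, V, D (high-pass along rows, along
columns, and along both).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "WaveletFilterPair",
    "SubbandSet",
    "AdmissibilityResult",
    "get_wavelet",
    "check_admissibility",
    "dwt2",
    "idwt2",
    "multilevel_dwt",
    "dwft2",
    "subband_energy_features",
]

_SQRT2 = math.sqrt(2.0)

# Orthonormal Daubechies scaling (low-pass analysis) coefficients, h0 first.
_SCALING_TAPS = {
    "haar": [1 / _SQRT2, 1 / _SQRT2],
    "db2": [
        (1 + math.sqrt(3)) / (4 * _SQRT2),
        (3 + math.sqrt(3)) / (4 * _SQRT2),
        (3 - math.sqrt(3)) / (4 * _SQRT2),
        (1 - math.sqrt(3)) / (4 * _SQRT2),
    ],
    "db4": [
        0.23037781330885523, 0.7148465705525415, 0.6308807679295904,
        -0.02798376941698385, -0.18703481171888114, 0.030841381835986965,
        0.032883011666982945, -0.010597401784997278,
    ],
}


@dataclass(frozen=True)
class WaveletFilterPair:
    """Analysis filter pair of an orthonormal two-channel filter bank."""

    h: np.ndarray  # low-pass taps
    g: np.ndarray  # high-pass taps (quadrature mirror of h)
    name: str = "custom"

    def __post_init__(self) -> None:
        h = np.asarray(self.h, dtype=float)
        g = np.asarray(self.g, dtype=float)
        if h.size == 0 or g.size == 0 or not (np.isfinite(h).all() and np.isfinite(g).all()):
            raise ValueError("filters must be non-empty and finite")
        object.__setattr__(self, "h", h)
        object.__setattr__(self, "g", g)


def get_wavelet(name: str = "haar") -> WaveletFilterPair:
    """Filter pair of a named orthonormal family (haar, db2, db4).

    The high-pass filter is the quadrature mirror ``g[k] = (-1)^k h[L-1-k]``,
    so ``sum h_k^2 = 1`` and ``sum g_k = 0``.
    """
    try:
        h = np.array(_SCALING_TAPS[name])
    except KeyError:
        raise ValueError(f"unknown wavelet {name!r}; choose from {sorted(_SCALING_TAPS)}")
    signs = (-1.0) ** np.arange(h.size)
    g = signs * h[::-1]
    return WaveletFilterPair(h=h, g=g, name=name)


@dataclass(frozen=True)
class SubbandSet:
    """A/H/V/D coefficient rasters of one decomposition level."""

    a: np.ndarray  # approximation (low/low)
    h: np.ndarray  # horizontal detail (high-pass along rows)
    v: np.ndarray  # vertical detail (high-pass along columns)
    d: np.ndarray  # diagonal detail (high-pass along both)
    level: int = 1
    decimated: bool = True

    def bands(self) -> dict[str, np.ndarray]:
        return {"A": self.a, "H": self.h, "V": self.v, "D": self.d}


@dataclass(frozen=True)
class AdmissibilityResult:
    passed: bool
    energy: float
    integral: float
    energy_finite: bool = field(default=True)
    zero_mean: bool = field(default=True)


def check_admissibility(mother_samples: np.ndarray, dt: float,
                        t: np.ndarray | None = None,
                        energy_bound: float = 1e12) -> AdmissibilityResult:
    """Numerically test the two wavelet admissibility conditions.

    A sampled candidate mother function passes iff its energy integral
    ``∫ |psi|^2 dt`` is finite (below *energy_bound*) and its plain integral
    ``∫ psi dt`` vanishes (|integral| below ``1e-6`` times the grid span).
    """
    psi = np.asarray(mother_samples, dtype=float)
    if psi.ndim != 1 or psi.size < 2:
        raise ValueError("need at least 2 samples of the mother function")
    if dt <= 0:
        raise ValueError("grid spacing must be positive")
    if t is not None:
        steps = np.diff(np.asarray(t, dtype=float))
        if not np.allclose(steps, steps[0], rtol=1e-9, atol=1e-12):
            raise ValueError("sample grid is not uniform")
    span = psi.size * dt
    energy = float(np.sum(psi**2) * dt)
    integral = float(np.sum(psi) * dt)
    energy_finite = bool(np.isfinite(energy) and energy < energy_bound)
    zero_mean = bool(abs(integral) < 1e-6 * span)
    return AdmissibilityResult(passed=energy_finite and zero_mean,
                               energy=energy, integral=integral,
                               energy_finite=energy_finite, zero_mean=zero_mean)


def _circ_filter(x: np.ndarray, taps: np.ndarray, axis: int) -> np.ndarray:
    """Circular convolution y[n] = sum_k f[k] x[n - k] along *axis*."""
    out = np.zeros_like(x, dtype=float)
    for k, fk in enumerate(taps):
        out += fk * np.roll(x, k, axis=axis)
    return out


def _upsampled(taps: np.ndarray, step: int) -> np.ndarray:
    """Filter taps with ``step - 1`` zeros inserted between them (a trous)."""
    if step == 1:
        return taps
    out = np.zeros((taps.size - 1) * step + 1)
    out[::step] = taps
    return out


def dwt2(img: np.ndarray, filters: WaveletFilterPair | None = None) -> SubbandSet:
    """One level of the separable 2-D DWT with periodic extension.

    Rows and columns are filtered with the low/high-pass pair and dyadically
    downsampled keeping even indices; the four filter combinations give the
    A, H, V and D sub-bands (each ``ceil(n/2)`` per axis).
    """
    filters = filters or get_wavelet()
    x = np.asarray(img, dtype=float)
    if x.ndim != 2 or min(x.shape) < 2:
        raise ValueError(f"input must be at least 2x2, got shape {x.shape}")
    lo_r = _circ_filter(x, filters.h, axis=0)[::2, :]
    hi_r = _circ_filter(x, filters.g, axis=0)[::2, :]
    a = _circ_filter(lo_r, filters.h, axis=1)[:, ::2]
    v = _circ_filter(lo_r, filters.g, axis=1)[:, ::2]
    h = _circ_filter(hi_r, filters.h, axis=1)[:, ::2]
    d = _circ_filter(hi_r, filters.g, axis=1)[:, ::2]
    return SubbandSet(a=a, h=h, v=v, d=d, level=1, decimated=True)


def _synth1(lo: np.ndarray, hi: np.ndarray, filters: WaveletFilterPair,
            n: int, axis: int) -> np.ndarray:
    """Inverse of one-axis analysis: transpose of the decimated filter map."""
    shape = list(lo.shape)
    shape[axis] = n
    out = np.zeros(shape)
    up_lo = np.zeros(shape)
    up_hi = np.zeros(shape)
    sl = [slice(None)] * lo.ndim
    sl[axis] = slice(0, n, 2)
    up_lo[tuple(sl)] = lo
    up_hi[tuple(sl)] = hi
    # transpose of y[i] = sum_m f[2i - m] x[m]  is  x[m] = sum_i y[i] f[2i - m]
    for k, fk in enumerate(filters.h):
        out += fk * np.roll(up_lo, -k, axis=axis)
    for k, fk in enumerate(filters.g):
        out += fk * np.roll(up_hi, -k, axis=axis)
    return out


def idwt2(bands: SubbandSet, filters: WaveletFilterPair | None = None) -> np.ndarray:
    """Synthesis transform; exact inverse of :func:`dwt2` for orthonormal
    filters on even-sized inputs."""
    filters = filters or get_wavelet()
    a, h, v, d = bands.a, bands.h, bands.v, bands.d
    if not (a.shape == h.shape == v.shape == d.shape):
        raise ValueError("sub-band shapes are inconsistent")
    rows2, cols2 = a.shape
    n_cols = cols2 * 2
    n_rows = rows2 * 2
    lo_r = _synth1(a, v, filters, n_cols, axis=1)
    hi_r = _synth1(h, d, filters, n_cols, axis=1)
    return _synth1(lo_r, hi_r, filters, n_rows, axis=0)


def multilevel_dwt(img: np.ndarray, filters: WaveletFilterPair | None = None,
                   level: int = 3) -> list[SubbandSet]:
    """Cascade of :func:`dwt2` applied recursively to the approximation."""
    if level < 1:
        raise ValueError("level must be >= 1")
    filters = filters or get_wavelet()
    out: list[SubbandSet] = []
    current = np.asarray(img, dtype=float)
    for lev in range(1, level + 1):
        bands = dwt2(current, filters)
        out.append(SubbandSet(a=bands.a, h=bands.h, v=bands.v, d=bands.d,
                              level=lev, decimated=True))
        current = bands.a
    return out


def dwft2(img: np.ndarray, filters: WaveletFilterPair | None = None,
          level: int = 1) -> list[SubbandSet]:
    """Undecimated wavelet frame transform (a trous scheme).

    No downsampling is performed; at level ``j`` the filters are upsampled by
    ``2^(j-1)``.  Every sub-band keeps the input shape, and circularly
    shifting the input circularly shifts every sub-band by the same amount.
    """
    if level < 1:
        raise ValueError("level must be >= 1")
    filters = filters or get_wavelet()
    x = np.asarray(img, dtype=float)
    if x.ndim != 2 or min(x.shape) < 2:
        raise ValueError(f"input must be at least 2x2, got shape {x.shape}")
    out: list[SubbandSet] = []
    approx = x
    for lev in range(1, level + 1):
        step = 2 ** (lev - 1)
        h = _upsampled(filters.h, step)
        g = _upsampled(filters.g, step)
        if h.size > min(x.shape):
            raise ValueError(
                f"filter support {h.size} at level {lev} exceeds image extent "
                f"{min(x.shape)}")
        lo_r = _circ_filter(approx, h, axis=0)
        hi_r = _circ_filter(approx, g, axis=0)
        a = _circ_filter(lo_r, h, axis=1)
        v = _circ_filter(lo_r, g, axis=1)
        hh = _circ_filter(hi_r, h, axis=1)
        d = _circ_filter(hi_r, g, axis=1)
        out.append(SubbandSet(a=a, h=hh, v=v, d=d, level=lev, decimated=False))
        approx = a
    return out


def subband_energy_features(bands: list[SubbandSet],
                            include_log: bool = False) -> dict[str, float]:
    """Normalized sub-band energies (mean squared coefficient) as named
    features.

    Order: the deepest approximation first, then H, V, D per level from
    shallow to deep — ``3 * levels + 1`` values.  With *include_log*, a
    ``log1p`` companion of each energy is appended.
    """
    if not bands:
        raise ValueError("no sub-bands given")
    deepest = bands[-1]
    feats: dict[str, float] = {
        f"wav_energy_A{deepest.level}": float(np.mean(deepest.a**2))
    }
    for b in bands:
        for key, band in (("H", b.h), ("V", b.v), ("D", b.d)):
            feats[f"wav_energy_{key}{b.level}"] = float(np.mean(band**2))
    if include_log:
        for name, val in list(feats.items()):
            feats[name.replace("wav_energy", "wav_logenergy")] = math.log1p(val)
    return feats
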