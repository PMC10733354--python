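"""Seeded synthetic brain-MRI phantoms with ground-truth tumor masks.

A phantom is a bimodal axial-slice caricature: an elliptical "brain" of one
intensity class on a dark background, optionally containing a hyperintense
elliptical "tumor", plus additive Gaussian (optionally Rician) noise and an
optional smooth multiplicative bias field.  The ground-truth mask is the
exact rasterized tumor ellipse, independent of noise.

The benign/malignant distinction of the dataset generator is a testing
convention — benign phantoms carry small, round tumors and malignant ones
large, eccentric tumors — not a claim about pathology.
"""

from __future__ import annotations

import math
import os
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from . import imgio

__all__ = ["PhantomSpec", "generate_phantom", "generate_dataset", "CLASS_RANGES"]

#: tumor area fraction of the brain area above which the label is malignant
MALIGNANT_AREA_FRACTION = 0.04


@dataclass(frozen=True)
class PhantomSpec:
    height: int = 64
    width: int = 64
    brain_axes: tuple[float, float] = (24.0, 20.0)   # (semi-row, semi-col)
    brain_intensity: int = 120
    background_intensity: int = 10
    tumor_present: bool = True
    tumor_center: tuple[float, float] = (28.0, 36.0)
    tumor_axes: tuple[float, float] = (6.0, 5.0)
    tumor_angle: float = 0.0           # radians
    tumor_intensity: int = 200
    noise_sigma: float = 5.0           # gray levels
    noise_model: str = "gaussian"      # {"gaussian", "rician"}
    bias_amplitude: float = 0.0        # in [0, 1)
    texture_sigma: float = 0.0         # within-region intensity jitter
    levels: int = 256
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.background_intensity < self.brain_intensity
                < self.tumor_intensity <= self.levels - 1):
            raise ValueError("intensities must satisfy background < brain < tumor")
        if not 0.0 <= self.bias_amplitude < 1.0:
            raise ValueError("bias_amplitude must lie in [0, 1)")


def _ellipse_mask(shape: tuple[int, int], center: tuple[float, float],
                  axes: tuple[float, float], angle: float = 0.0) -> np.ndarray:
    """Pixels whose centers lie strictly inside the ellipse."""
    rr, cc = np.indices(shape)
    dr = rr - center[0]
    dc = cc - center[1]
    ca, sa = math.cos(angle), math.sin(angle)
    u = ca * dr + sa * dc
    w = -sa * dr + ca * dc
    return (u / axes[0]) ** 2 + (w / axes[1]) ** 2 < 1.0


def _check_containment(spec: PhantomSpec, tumor: np.ndarray,
                       brain: np.ndarray) -> None:
    if spec.tumor_present and not (tumor <= brain).all():
        raise ValueError("tumor ellipse is not contained in the brain ellipse")


def generate_phantom(spec: PhantomSpec) -> tuple[np.ndarray, np.ndarray, str]:
    """Rasterize one phantom; returns (image, ground-truth mask, label).

    Labels: ``none`` when no tumor is present, otherwise ``malignant`` if
    the tumor area reaches ``MALIGNANT_AREA_FRACTION`` of the brain area,
    else ``benign``.  Bit-identical given the same spec (the seed lives in
    the spec).
    """
    rng = np.random.default_rng(spec.seed)
    shape = (spec.height, spec.width)
    center = ((spec.height - 1) / 2.0, (spec.width - 1) / 2.0)
    brain = _ellipse_mask(shape, center, spec.brain_axes)
    img = np.full(shape, float(spec.background_intensity))
    img[brain] = spec.brain_intensity
    if spec.tumor_present:
        tumor = _ellipse_mask(shape, spec.tumor_center, spec.tumor_axes,
                              spec.tumor_angle)
        _check_containment(spec, tumor, brain)
        img[tumor] = spec.tumor_intensity
    else:
        tumor = np.zeros(shape, dtype=bool)
    if spec.texture_sigma > 0:
        img += rng.normal(0.0, spec.texture_sigma, shape) * brain
    if spec.bias_amplitude > 0:
        rr, cc = np.indices(shape)
        u = 2.0 * rr / (spec.height - 1) - 1.0
        w = 2.0 * cc / (spec.width - 1) - 1.0
        coeffs = rng.uniform(-1.0, 1.0, size=5)
        poly = coeffs[0] * u + coeffs[1] * w + coeffs[2] * u * w \
            + coeffs[3] * u**2 + coeffs[4] * w**2
        poly /= max(1.0, np.abs(poly).max())
        img *= 1.0 + spec.bias_amplitude * poly
    if spec.noise_sigma > 0:
        if spec.noise_model == "gaussian":
            img += rng.normal(0.0, spec.noise_sigma, shape)
        elif spec.noise_model == "rician":
            re = img + rng.normal(0.0, spec.noise_sigma, shape)
            im = rng.normal(0.0, spec.noise_sigma, shape)
            img = np.hypot(re, im)
        else:
            raise ValueError(f"unknown noise model {spec.noise_model!r}")
    img = np.clip(np.rint(img), 0, spec.levels - 1).astype(np.int64)
    if not spec.tumor_present:
        label = "none"
    else:
        frac = tumor.sum() / max(1, brain.sum())
        label = "malignant" if frac >= MALIGNANT_AREA_FRACTION else "benign"
    return img, tumor, label


#: sampling ranges per class: (tumor axes low/high, eccentricity via axis ratio)
CLASS_RANGES = {
    "none": None,
    "benign": {"axis": (3.5, 5.0), "ratio": (0.85, 1.0)},
    "malignant": {"axis": (7.0, 10.0), "ratio": (0.45, 0.7)},
    # generic "tumor" class: the union of benign and malignant ranges
    "tumor": {"axis": (3.5, 10.0), "ratio": (0.45, 1.0)},
}


def _sample_spec(cls: str, base: PhantomSpec, rng: np.random.Generator) -> PhantomSpec:
    seed = int(rng.integers(0, 2**31 - 1))
    if cls == "none":
        return replace(base, tumor_present=False, seed=seed)
    rngs = CLASS_RANGES[cls]
    major = rng.uniform(*rngs["axis"])
    minor = major * rng.uniform(*rngs["ratio"])
    angle = rng.uniform(0.0, math.pi)
    # place the tumor center so the tumor stays inside the brain ellipse
    center = ((base.height - 1) / 2.0, (base.width - 1) / 2.0)
    margin = major + 1.0
    for _ in range(100):
        t = rng.uniform(0.0, 2 * math.pi)
        rho = rng.uniform(0.0, 1.0) ** 0.5
        dr = rho * (base.brain_axes[0] - margin) * math.sin(t)
        dc = rho * (base.brain_axes[1] - margin) * math.cos(t)
        cand = replace(base, tumor_present=True,
                       tumor_center=(center[0] + dr, center[1] + dc),
                       tumor_axes=(major, minor), tumor_angle=angle, seed=seed)
        shape = (base.height, base.width)
        brain = _ellipse_mask(shape, center, base.brain_axes)
        tumor = _ellipse_mask(shape, cand.tumor_center, cand.tumor_axes, angle)
        if (tumor <= brain).all() and tumor.sum() >= 16:
            return cand
    raise ValueError("could not place a tumor inside the brain ellipse")


def generate_dataset(n_per_class: int, classes: tuple[str, ...] = ("benign", "malignant"),
                     base_spec: PhantomSpec | None = None, seed: int = 0,
                     out_dir: str | os.PathLike | None = None) -> pd.DataFrame:
    """Sample a labelled phantom dataset; deterministic given *seed*.

    Returns a manifest DataFrame with columns ``image_id``, ``label`` and a
    ``spec`` column holding each phantom's fully resolved spec.  With
    *out_dir*, images and masks are written as PNG plus a ``labels.csv``.
    """
    if n_per_class < 1:
        raise ValueError("n_per_class must be >= 1")
    unknown = set(classes) - set(CLASS_RANGES)
    if unknown:
        raise ValueError(f"unknown classes: {sorted(unknown)}")
    base = base_spec or PhantomSpec()
    rng = np.random.default_rng(seed)
    rows = []
    for cls in classes:
        for i in range(n_per_class):
            spec = _sample_spec(cls, base, rng)
            img, mask, _ = generate_phantom(spec)
            image_id = f"{cls}_{i:04d}"
            rows.append({"image_id": image_id, "label": cls, "spec": spec,
                         "image": img, "mask": mask})
    manifest = pd.DataFrame(rows)
    if out_dir is not None:
        os.makedirs(out_dir, exist_ok=True)
        for row in rows:
            imgio.save_image(row["image"], os.path.join(out_dir, f"{row['image_id']}.png"))
            imgio.save_mask(row["mask"], os.path.join(out_dir, f"{row['image_id']}_mask.png"))
        manifest[["image_id", "label"]].to_csv(
            os.path.join(out_dir, "labels.csv"), index=False)
    return manifest
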