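"""End-to-end tumor detection: preprocess -> segment -> morphology ->
pixel-count decision -> features -> PCA -> SVM -> scores.

Segmentation is two-stage global thresholding by default: a first Otsu
threshold separates the head from the dark background, a second one —
computed on brain-interior intensities only — separates the hyperintense
tumor from normal tissue.  Each stage carries a contrast guard: when the
separation between the two class means falls below ``min_gap`` gray levels
the stage declares "nothing to split" and returns an empty mask, which is
what makes a blank or tumor-free image land in the no-tumor branch of the
pixel-count rule instead of thresholding pure noise.  The
nonlocal-regularized FCM segmenter is selectable for the second stage.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from . import imgio, metrics, nlfcm, otsu, pca, postseg, svmclf, texture
from .postseg import TumorRegion

__all__ = ["PipelineConfig", "segment_tumor", "extract_features",
           "run_detect", "run_experiment", "DEFAULT_KERNELS"]

logger = logging.getLogger(__name__)

DEFAULT_KERNELS = ("linear", "quadratic", "polynomial", "rbf")


@dataclass(frozen=True)
class PipelineConfig:
    levels: int = 256
    denoise_method: str | None = None           # {"median", "average", None}
    denoise_window: int = 3
    segmenter: str = "otsu"                     # {"otsu", "nlfcm"}
    fcm: nlfcm.FCMConfig = field(default_factory=nlfcm.FCMConfig)
    min_gap: float = 25.0                       # contrast guard, gray levels
    open_radius: int = 0
    min_area: int = 16
    glcm: texture.GLCMConfig = field(default_factory=texture.GLCMConfig)
    wavelet: texture.WaveletFeatureConfig = field(default_factory=texture.WaveletFeatureConfig)
    pca_fraction: float = 0.95
    kernels: tuple[str, ...] = DEFAULT_KERNELS
    C: float = 1.0
    gamma: float | None = None
    test_fraction: float = 0.3
    seed: int = 0


def _otsu_split(img: np.ndarray, within: np.ndarray | None, levels: int,
                min_gap: float) -> tuple[np.ndarray, float]:
    """Threshold the (optionally masked) image; empty mask when the class
    mean separation is below *min_gap*.  Returns (mask, mean gap)."""
    values = img if within is None else img[within]
    if values.size == 0:
        return np.zeros(img.shape, dtype=bool), 0.0
    counts = np.bincount(np.asarray(values, dtype=np.int64).ravel(), minlength=levels)
    hist = otsu.Histogram(counts=counts, probs=counts / counts.sum(),
                          n_pixels=int(counts.sum()), levels=levels)
    if np.count_nonzero(counts) < 2:
        return np.zeros(img.shape, dtype=bool), 0.0
    k = otsu.otsu_threshold(hist)
    stats = otsu.class_statistics(hist, k)
    gap = stats.mu_y - stats.mu_x
    if gap < min_gap:
        return np.zeros(img.shape, dtype=bool), gap
    mask = otsu.binarize(img, k + 1, levels=levels)
    if within is not None:
        mask = mask & within
    return mask, gap


def segment_tumor(img: np.ndarray, cfg: PipelineConfig | None = None) -> np.ndarray:
    """Raw (pre-morphology) tumor candidate mask of a preprocessed image."""
    cfg = cfg or PipelineConfig()
    brain, _ = _otsu_split(img, None, cfg.levels, cfg.min_gap)
    if not brain.any():
        return brain
    if cfg.segmenter == "otsu":
        mask, _ = _otsu_split(img, brain, cfg.levels, cfg.min_gap)
        return mask
    if cfg.segmenter == "nlfcm":
        # brain masking with a neutral fill so c=2 separates tissue vs tumor
        filled = img.copy()
        filled[~brain] = int(np.median(img[brain]))
        state, labels = nlfcm.segment(filled, cfg.fcm, levels=cfg.levels)
        bright = int(np.argmax(state.v))
        if np.ptp(state.v) < cfg.min_gap:
            return np.zeros(img.shape, dtype=bool)
        return (labels == bright) & brain
    raise ValueError(f"unknown segmenter {cfg.segmenter!r}")


def _preprocess(img: np.ndarray, cfg: PipelineConfig) -> np.ndarray:
    if cfg.denoise_method is None:
        return imgio.validate_gray_image(img, levels=cfg.levels)
    return imgio.denoise(img, method=cfg.denoise_method,
                         window=cfg.denoise_window, levels=cfg.levels)


def extract_features(img: np.ndarray, cfg: PipelineConfig | None = None
                     ) -> tuple[dict[str, float], TumorRegion]:
    """Segment one image and compute its feature vector.

    Features are computed on the segmented tumor region, falling back to the
    whole image when no region survives the pixel-count rule.
    """
    cfg = cfg or PipelineConfig()
    pre = _preprocess(img, cfg)
    raw = segment_tumor(pre, cfg)
    clean = postseg.morphological_clean(raw, cfg.open_radius, cfg.min_area)
    region = postseg.extract_tumor(clean)
    mask = region.mask if region.present else None
    feats = texture.extract_feature_vector(pre, mask, cfg.glcm, cfg.wavelet,
                                           levels=cfg.levels)
    return feats, region


def run_detect(img: np.ndarray, cfg: PipelineConfig, model: svmclf.SVMModel
               ) -> tuple[TumorRegion, str, dict[str, float]]:
    """Single-image detection with the pixel-count short-circuit.

    A zero-pixel tumor region yields the label ``"no tumor"`` without
    invoking the classifier; otherwise the feature vector of the region is
    classified with the trained model.
    """
    feats, region = extract_features(img, cfg)
    if not region.present:
        return region, "no tumor", feats
    names = texture.feature_names(cfg.wavelet)
    X = np.array([[feats[n] for n in names]])
    label = str(svmclf.predict(model, X, feature_names=tuple(names))[0])
    return region, label, feats


def _kernel_spec(kind: str, cfg: PipelineConfig) -> svmclf.KernelSpec:
    return svmclf.KernelSpec(kind=kind, C=cfg.C, gamma=cfg.gamma)


def run_experiment(manifest: pd.DataFrame, cfg: PipelineConfig | None = None
                   ) -> dict:
    """Train and score every configured kernel on a phantom manifest.

    The manifest needs columns ``image_id``, ``label``, ``image`` and
    (optionally) ``mask`` with the ground-truth tumor mask.  Features go
    through PCA fitted on the training split; scores are computed on the
    held-out split with the non-"none" class as positive.  Returns a
    JSON-serializable report including segmentation Dice statistics.
    """
    cfg = cfg or PipelineConfig()
    labels = manifest["label"].to_numpy()
    classes = sorted(set(labels.tolist()))
    if len(classes) != 2 or min((labels == c).sum() for c in classes) < 2:
        raise ValueError("need >= 2 images in each of exactly 2 classes; "
                         "generate a larger dataset")
    names = texture.feature_names(cfg.wavelet)
    rows, dices = [], []
    t0 = time.perf_counter()
    for _, rec in manifest.iterrows():
        feats, region = extract_features(np.asarray(rec["image"]), cfg)
        rows.append([feats[n] for n in names])
        if "mask" in manifest.columns and rec["mask"] is not None:
            dices.append(metrics.dice(region.mask, np.asarray(rec["mask"])))
    logger.info("feature extraction for %d images took %.1fs",
                len(rows), time.perf_counter() - t0)
    X = np.asarray(rows)
    X_tr, X_te, y_tr, y_te = svmclf.stratified_split(
        X, labels, test_fraction=cfg.test_fraction, seed=cfg.seed)
    pca_model = pca.fit_pca(X_tr, cfg.pca_fraction, feature_names=tuple(names))
    Z_tr = pca.transform(pca_model, X_tr)
    Z_te = pca.transform(pca_model, X_te)
    positive = next((c for c in classes if c != "none"), classes[1])
    report: dict = {
        "n_images": int(len(manifest)),
        "classes": classes,
        "positive_label": positive,
        "n_train": int(len(y_tr)),
        "n_test": int(len(y_te)),
        "pca_components": int(pca_model.n_components),
        "kernels": {},
    }
    if dices:
        report["dice"] = {"mean": float(np.mean(dices)),
                          "min": float(np.min(dices)),
                          "max": float(np.max(dices))}
    for kind in cfg.kernels:
        model = svmclf.train_svm(Z_tr, y_tr, _kernel_spec(kind, cfg), seed=cfg.seed)
        pred = svmclf.predict(model, Z_te)
        cm = metrics.confusion(y_te, pred, positive=positive)
        sc = metrics.scores(cm)
        report["kernels"][kind] = {
            "recall": sc.recall, "precision": sc.precision,
            "f_measure": sc.f_measure, "accuracy": sc.accuracy,
            "confusion": asdict(cm),
        }
    return report


def save_report(report: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(report, fh, indent=1)
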