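"""Principal component analysis of the feature table.

Features are z-scored (constant columns get unit scale) before the sample
covariance of the standardized table is eigendecomposed.  Components are
ordered by descending eigenvalue with a deterministic sign convention — the
loading of largest magnitude is made positive — so serialized models
reproduce bit-identically.  The retained count is the smallest one whose
cumulative explained-variance ratio reaches the requested fraction.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass

import numpy as np

__all__ = ["PCAModel", "fit_pca", "transform", "inverse_transform",
           "save_model", "load_model"]


@dataclass(frozen=True)
class PCAModel:
    mean_vector: np.ndarray        # per-feature training means
    scale_vector: np.ndarray       # per-feature training stds (1 for constants)
    components: np.ndarray         # (n_components, n_features), orthonormal rows
    explained_variance: np.ndarray  # all eigenvalues, descending
    n_components: int
    feature_names: tuple[str, ...] | None = None

    @property
    def explained_variance_ratio(self) -> np.ndarray:
        total = self.explained_variance.sum()
        return self.explained_variance / total if total > 0 else self.explained_variance


def _standardize(X: np.ndarray, mean: np.ndarray, scale: np.ndarray) -> np.ndarray:
    return (X - mean) / scale


def fit_pca(X: np.ndarray, variance_fraction: float = 0.95,
            feature_names: tuple[str, ...] | None = None) -> PCAModel:
    """Fit a PCA retaining enough components to explain *variance_fraction*."""
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2 or X.shape[1] < 1:
        raise ValueError("need a 2-D table with at least 2 samples and 1 feature")
    if not 0.0 < variance_fraction <= 1.0:
        raise ValueError("variance_fraction must lie in (0, 1]")
    mean = X.mean(axis=0)
    scale = X.std(axis=0, ddof=1)
    scale = np.where(scale > 0, scale, 1.0)
    Z = _standardize(X, mean, scale)
    cov = np.cov(Z, rowvar=False, ddof=1)
    cov = np.atleast_2d(cov)
    eigvals, eigvecs = np.linalg.eigh(cov)
    order = np.argsort(eigvals)[::-1]
    eigvals = np.clip(eigvals[order], 0.0, None)
    comps = eigvecs[:, order].T           # rows are components
    # deterministic sign: largest-magnitude loading positive
    for row in comps:
        idx = np.argmax(np.abs(row))
        if row[idx] < 0:
            row *= -1.0
    total = eigvals.sum()
    if total <= 0:
        n_keep = 1
    else:
        cum = np.cumsum(eigvals) / total
        n_keep = int(np.searchsorted(cum, variance_fraction - 1e-12) + 1)
        n_keep = min(n_keep, len(eigvals))
    return PCAModel(mean_vector=mean, scale_vector=scale,
                    components=comps[:n_keep], explained_variance=eigvals,
                    n_components=n_keep, feature_names=feature_names)


def transform(model: PCAModel, X: np.ndarray) -> np.ndarray:
    """Project standardized rows onto the retained components."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] != model.mean_vector.shape[0]:
        raise ValueError(f"expected {model.mean_vector.shape[0]} features, "
                         f"got {X.shape[1]}")
    return _standardize(X, model.mean_vector, model.scale_vector) @ model.components.T


def inverse_transform(model: PCAModel, scores: np.ndarray) -> np.ndarray:
    """Map component scores back to (standardized) feature space, then undo
    the standardization.  Exact only when all components are retained."""
    scores = np.atleast_2d(np.asarray(scores, dtype=float))
    Z = scores @ model.components
    return Z * model.scale_vector + model.mean_vector


def save_model(model: PCAModel, path: str | os.PathLike) -> None:
    payload = {
        "mean_vector": model.mean_vector.tolist(),
        "scale_vector": model.scale_vector.tolist(),
        "components": model.components.tolist(),
        "explained_variance": model.explained_variance.tolist(),
        "n_components": model.n_components,
        "feature_names": list(model.feature_names) if model.feature_names else None,
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1)


def load_model(path: str | os.PathLike) -> PCAModel:
    with open(path) as fh:
        d = json.load(fh)
    return PCAModel(
        mean_vector=np.array(d["mean_vector"]),
        scale_vector=np.array(d["scale_vector"]),
        components=np.array(d["components"]),
        explained_variance=np.array(d["explained_variance"]),
        n_components=int(d["n_components"]),
        feature_names=tuple(d["feature_names"]) if d["feature_names"] else None,
    )
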