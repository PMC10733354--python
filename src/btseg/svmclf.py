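"""Kernel functions and binary SVM training/prediction.

Kernels use the canonical forms: linear ``x . y``, polynomial
``(gamma x . y + coef0)^degree`` ("quadratic" is the degree-2 case), and RBF
``exp(-gamma ||x - y||^2)``.  Training delegates the soft-margin dual to the
libsvm solver behind :class:`sklearn.svm.SVC`; prediction evaluates the
stored decision function with this module's own kernels.  Features are
z-scored with training-set statistics before any kernel evaluation.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field

import numpy as np
from sklearn.model_selection import StratifiedKFold, train_test_split
from sklearn.svm import SVC

__all__ = [
    "KernelSpec",
    "SVMModel",
    "kernel_eval",
    "gram_matrix",
    "train_svm",
    "predict",
    "decision_function",
    "stratified_split",
    "grid_search",
    "save_model",
    "load_model",
]

_KINDS = ("linear", "polynomial", "quadratic", "rbf")


@dataclass(frozen=True)
class KernelSpec:
    kind: str = "rbf"
    gamma: float | None = None   # None: 1 / n_features at fit time
    degree: int = 3
    coef0: float = 1.0
    C: float = 1.0

    def __post_init__(self) -> None:
        if self.kind not in _KINDS:
            raise ValueError(f"kernel kind must be one of {_KINDS}")
        if self.kind == "quadratic":
            object.__setattr__(self, "degree", 2)
        if self.gamma is not None and self.gamma <= 0:
            raise ValueError("gamma must be positive")
        if self.C <= 0:
            raise ValueError("C must be positive")


@dataclass(frozen=True)
class SVMModel:
    spec: KernelSpec
    support_vectors: np.ndarray    # standardized training rows
    dual_coefficients: np.ndarray  # y_i alpha_i per support vector
    intercept: float
    classes: tuple                 # (negative, positive) decision-sign order
    gamma: float                   # resolved gamma actually used
    scaler_mean: np.ndarray
    scaler_scale: np.ndarray
    feature_names: tuple[str, ...] | None = field(default=None, compare=False)


def kernel_eval(spec: KernelSpec, x: np.ndarray, y: np.ndarray,
                gamma: float | None = None) -> float:
    """Kernel value of a single vector pair."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("vector lengths differ")
    g = gamma if gamma is not None else (spec.gamma or 1.0 / x.size)
    if spec.kind == "linear":
        return float(x @ y)
    if spec.kind in ("polynomial", "quadratic"):
        return float((g * (x @ y) + spec.coef0) ** spec.degree)
    return float(np.exp(-g * np.sum((x - y) ** 2)))


def gram_matrix(spec: KernelSpec, X: np.ndarray, Y: np.ndarray | None = None,
                gamma: float | None = None) -> np.ndarray:
    """Pairwise kernel values; symmetric PSD (up to round-off) when Y is X."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    Y = X if Y is None else np.atleast_2d(np.asarray(Y, dtype=float))
    if X.size == 0:
        raise ValueError("empty input")
    g = gamma if gamma is not None else (spec.gamma or 1.0 / X.shape[1])
    if spec.kind == "linear":
        return X @ Y.T
    if spec.kind in ("polynomial", "quadratic"):
        return (g * (X @ Y.T) + spec.coef0) ** spec.degree
    d2 = (np.sum(X**2, axis=1)[:, None] + np.sum(Y**2, axis=1)[None, :]
          - 2.0 * X @ Y.T)
    return np.exp(-g * np.maximum(d2, 0.0))


def _standardize_fit(X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    mean = X.mean(axis=0)
    scale = X.std(axis=0)
    return mean, np.where(scale > 0, scale, 1.0)


def train_svm(X: np.ndarray, y, spec: KernelSpec | None = None,
              seed: int = 0,
              feature_names: tuple[str, ...] | None = None) -> SVMModel:
    """Fit a binary soft-margin SVM on a feature table.

    Rows are sorted into a canonical order before solving so the result is
    independent of the input row order.
    """
    spec = spec or KernelSpec()
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y)
    if X.shape[0] != y.shape[0]:
        raise ValueError("X and y lengths differ")
    if not np.isfinite(X).all():
        bad = np.nonzero(~np.isfinite(X).all(axis=0))[0]
        names = ([feature_names[i] for i in bad] if feature_names
                 else bad.tolist())
        raise ValueError(f"non-finite values in feature columns: {names}")
    classes = tuple(sorted(np.unique(y).tolist()))
    if len(classes) != 2:
        raise ValueError(f"need exactly 2 classes, got {classes}")
    mean, scale = _standardize_fit(X)
    Z = (X - mean) / scale
    # canonical row order -> row-permutation-invariant solver input
    order = np.lexsort(np.vstack([Z.T, (y == classes[1]).astype(int)]))
    Z, yo = Z[order], y[order]
    gamma = spec.gamma if spec.gamma is not None else 1.0 / X.shape[1]
    sk_kernel = {"linear": "linear", "rbf": "rbf",
                 "polynomial": "poly", "quadratic": "poly"}[spec.kind]
    clf = SVC(kernel=sk_kernel, C=spec.C, gamma=gamma, degree=spec.degree,
              coef0=spec.coef0, tol=1e-6, random_state=seed)
    clf.fit(Z, yo)
    return SVMModel(spec=spec,
                    support_vectors=clf.support_vectors_.copy(),
                    dual_coefficients=clf.dual_coef_.ravel().copy(),
                    intercept=float(clf.intercept_[0]),
                    classes=tuple(clf.classes_.tolist()),
                    gamma=gamma, scaler_mean=mean, scaler_scale=scale,
                    feature_names=feature_names)


def decision_function(model: SVMModel, X: np.ndarray,
                      feature_names: tuple[str, ...] | None = None) -> np.ndarray:
    """Signed distance to the separating surface, evaluated with the
    package's own kernels against the stored support vectors."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.size == 0:
        return np.empty(0)
    if X.shape[1] != model.scaler_mean.shape[0]:
        raise ValueError(f"expected {model.scaler_mean.shape[0]} features, "
                         f"got {X.shape[1]}")
    if feature_names is not None and model.feature_names is not None \
            and tuple(feature_names) != tuple(model.feature_names):
        raise ValueError("feature names do not match the trained model")
    Z = (X - model.scaler_mean) / model.scaler_scale
    K = gram_matrix(model.spec, Z, model.support_vectors, gamma=model.gamma)
    return K @ model.dual_coefficients + model.intercept


def predict(model: SVMModel, X: np.ndarray,
            feature_names: tuple[str, ...] | None = None) -> np.ndarray:
    """Class labels from the sign of the decision function."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.size == 0:
        return np.array([], dtype=object)
    dec = decision_function(model, X, feature_names)
    out = np.where(dec > 0, model.classes[1], model.classes[0])
    return out


def stratified_split(X: np.ndarray, y, test_fraction: float = 0.3,
                     seed: int = 0):
    """Seeded stratified train/test split (70/30 by default)."""
    return train_test_split(np.asarray(X), np.asarray(y),
                            test_size=test_fraction, stratify=np.asarray(y),
                            random_state=seed)


def grid_search(X: np.ndarray, y, spec: KernelSpec,
                C_grid=(0.1, 1.0, 10.0), gamma_grid=(0.01, 0.1, 1.0),
                n_folds: int = 3, seed: int = 0) -> KernelSpec:
    """Seeded k-fold CV over C (and gamma for non-linear kernels)."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    gammas = gamma_grid if spec.kind != "linear" else (None,)
    best = (-np.inf, spec)
    cv = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    for C in C_grid:
        for g in gammas:
            cand = KernelSpec(kind=spec.kind, gamma=g, degree=spec.degree,
                              coef0=spec.coef0, C=C)
            accs = []
            for tr, te in cv.split(X, y):
                model = train_svm(X[tr], y[tr], cand, seed=seed)
                accs.append(float(np.mean(predict(model, X[te]) == y[te])))
            score = float(np.mean(accs))
            if score > best[0]:
                best = (score, cand)
    return best[1]


def save_model(model: SVMModel, path: str | os.PathLike) -> None:
    payload = {
        "spec": {"kind": model.spec.kind, "gamma": model.spec.gamma,
                 "degree": model.spec.degree, "coef0": model.spec.coef0,
                 "C": model.spec.C},
        "support_vectors": model.support_vectors.tolist(),
        "dual_coefficients": model.dual_coefficients.tolist(),
        "intercept": model.intercept,
        "classes": list(model.classes),
        "gamma": model.gamma,
        "scaler_mean": model.scaler_mean.tolist(),
        "scaler_scale": model.scaler_scale.tolist(),
        "feature_names": list(model.feature_names) if model.feature_names else None,
    }
    with open(path, "w") as fh:
        json.dump(payload, fh)


def load_model(path: str | os.PathLike) -> SVMModel:
    with open(path) as fh:
        d = json.load(fh)
    return SVMModel(
        spec=KernelSpec(**d["spec"]),
        support_vectors=np.array(d["support_vectors"]),
        dual_coefficients=np.array(d["dual_coefficients"]),
        intercept=float(d["intercept"]),
        classes=tuple(d["classes"]),
        gamma=float(d["gamma"]),
        scaler_mean=np.array(d["scaler_mean"]),
        scaler_scale=np.array(d["scaler_scale"]),
        feature_names=tuple(d["feature_names"]) if d["feature_names"] else None,
    )
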