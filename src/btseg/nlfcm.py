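"""Nonlocal-regularized fuzzy c-means (FCM) segmentation.

The segmenter minimizes a fuzzy clustering objective with two data terms per
pixel: a local one coupling the intensity ``x_k`` to the cluster center
through a normalized spatial kernel ``K`` over a neighborhood window, and a
nonlocal one coupling the patch-similarity-weighted mean ``xbar_k`` to the
same center with a per-pixel balance weight ``beta_k``,

    J_m = sum_i sum_k u_ik^m sum_{r in O_k} K(r-k) ||x_k - b(r) v_i||^2
        + sum_i sum_k [ a_k u_ik^m (1 - u_ik^{m-1})
                        + beta_k u_ik^m sum_{r in O_k} K(r-k) ||xbar_k - b(r) v_i||^2 ]

subject to memberships summing to one per pixel.  Alternating the
Lagrange-derived closed-form updates for the memberships ``u_ik`` and the
centers ``v_i`` decreases the objective monotonically.

``beta_k`` is a dispersion statistic of the pixel's normalized nonlocal
similarity weights, (max - mean) / mean: it vanishes in flat regions (all
patches alike) and grows near structure, shifting weight onto the nonlocal
regularizer exactly where plain intensities are unreliable.  The penalty
weight ``a_k`` defaults to zero and the bias multiplier ``b`` to one; both
are configurable inputs, not estimated quantities.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .imgio import validate_gray_image

__all__ = [
    "FCMConfig",
    "FCMState",
    "spatial_kernel",
    "nonlocal_mean",
    "compute_weights",
    "update_memberships",
    "update_centers",
    "objective",
    "segment",
]

logger = logging.getLogger(__name__)

_EPS = 1e-12  # clip for exact-hit / negative aggregated distances


@dataclass(frozen=True)
class FCMConfig:
    """Tunable parameters of the segmenter (gray-level units throughout)."""

    c: int = 2                   # cluster count
    m: float = 2.0               # fuzzifier, > 1
    window_radius: int = 1       # half-width of the local window O_k
    patch_radius: int = 1        # nonlocal patch half-width
    search_radius: int = 2       # nonlocal search-window half-width
    h_nl: float = 10.0           # nonlocal decay (RMS gray-level difference)
    a_mode: str = "zero"         # {"zero", "constant"}
    a_const: float = 0.0
    beta_mode: str = "dispersion"  # {"dispersion", "constant"}
    beta_const: float = 0.0
    max_iter: int = 100
    tol: float = 1e-5            # convergence threshold on max |du|
    seed: int = 0

    def __post_init__(self) -> None:
        if self.c < 2:
            raise ValueError("need at least 2 clusters")
        if self.m <= 1.0:
            raise ValueError("fuzzifier m must be > 1")
        if self.window_radius < 0 or self.patch_radius < 1 or self.search_radius < 1:
            raise ValueError("invalid window/patch/search radius")
        if self.h_nl <= 0:
            raise ValueError("h_nl must be positive")


@dataclass
class FCMState:
    """Everything the alternating optimization tracks."""

    u: np.ndarray                # memberships, (c, N)
    v: np.ndarray                # cluster centers, (c,)
    b: np.ndarray                # bias multipliers, (N,), default all 1
    xbar: np.ndarray             # nonlocal mean image, (N,)
    a: np.ndarray                # per-pixel penalty weight
    beta: np.ndarray             # per-pixel nonlocal balance weight
    objective_trace: list[float] = field(default_factory=list)
    n_iter: int = 0
    converged: bool = False


def spatial_kernel(radius: int) -> np.ndarray:
    """Truncated Gaussian weights (sigma = radius / 2) over the local window,
    normalized to sum 1.  Radius 0 gives the single weight 1."""
    if radius == 0:
        return np.ones((1, 1))
    ax = np.arange(-radius, radius + 1)
    dr, dc = np.meshgrid(ax, ax, indexing="ij")
    sigma = radius / 2.0
    k = np.exp(-(dr**2 + dc**2) / (2.0 * sigma**2))
    return k / k.sum()


def _search_offsets(radius: int) -> list[tuple[int, int]]:
    return [(dr, dc)
            for dr in range(-radius, radius + 1)
            for dc in range(-radius, radius + 1)
            if (dr, dc) != (0, 0)]


def nonlocal_mean(img: np.ndarray, patch_radius: int = 1, search_radius: int = 2,
                  h_nl: float = 10.0,
                  return_weights: bool = False):
    """Patch-similarity-weighted mean intensity with periodic boundaries.

    For each pixel the candidates are all offsets in the search window except
    the pixel itself; candidate weights are ``exp(-d2 / h^2)`` with ``d2``
    the mean squared difference between the two patches, normalized to sum 1
    over the window.  Returns the averaged raster (and optionally the
    normalized weight stack, one slice per offset).
    """
    x = np.asarray(img, dtype=float)
    if x.ndim != 2:
        raise ValueError("expected a 2-D raster")
    if patch_radius < 1 or search_radius < 1 or h_nl <= 0:
        raise ValueError("radii must be >= 1 and h_nl > 0")
    if 2 * search_radius + 1 > min(x.shape) or 2 * patch_radius + 1 > min(x.shape):
        raise ValueError("search/patch window larger than the image")
    offsets = _search_offsets(search_radius)
    size = 2 * patch_radius + 1
    weights = np.empty((len(offsets),) + x.shape)
    shifted = np.empty_like(weights)
    for idx, (dr, dc) in enumerate(offsets):
        sh = np.roll(x, (-dr, -dc), axis=(0, 1))  # value at k + offset
        diff2 = (x - sh) ** 2
        d2 = ndimage.uniform_filter(diff2, size=size, mode="wrap")
        weights[idx] = np.exp(-d2 / h_nl**2)
        shifted[idx] = sh
    total = weights.sum(axis=0)
    weights /= total  # exp > 0, so total > 0 always
    xbar = (weights * shifted).sum(axis=0)
    if return_weights:
        return xbar, weights
    return xbar


def compute_weights(img: np.ndarray, cfg: FCMConfig):
    """Per-pixel penalty weight ``a_k``, nonlocal balance ``beta_k``, and the
    nonlocal mean raster ``xbar``.

    ``beta_k = (max(w_k) - mean(w_k)) / mean(w_k)`` over the pixel's
    normalized nonlocal similarity weights; 0 where the mean vanishes.
    """
    xbar, w = nonlocal_mean(img, cfg.patch_radius, cfg.search_radius, cfg.h_nl,
                            return_weights=True)
    if cfg.beta_mode == "dispersion":
        mean_w = w.mean(axis=0)
        max_w = w.max(axis=0)
        beta = np.where(mean_w > 0, (max_w - mean_w) / np.where(mean_w > 0, mean_w, 1.0), 0.0)
    elif cfg.beta_mode == "constant":
        beta = np.full(img.shape, float(cfg.beta_const))
    else:
        raise ValueError(f"unknown beta_mode {cfg.beta_mode!r}")
    if cfg.a_mode == "zero":
        a = np.zeros(img.shape)
    elif cfg.a_mode == "constant":
        a = np.full(img.shape, float(cfg.a_const))
    else:
        raise ValueError(f"unknown a_mode {cfg.a_mode!r}")
    return a.ravel(), beta.ravel(), xbar.ravel()


def _aggregated_distance(x: np.ndarray, xbar: np.ndarray, v: np.ndarray,
                         b: np.ndarray, a: np.ndarray, beta: np.ndarray) -> np.ndarray:
    """D_ik = ||x_k - b_k v_i||^2 - a_k + beta_k ||xbar_k - b_k v_i||^2.

    The normalized kernel sum over the window collapses because every term
    is constant over the window offsets.
    """
    bv = b[None, :] * v[:, None]          # (c, N)
    return (x[None, :] - bv) ** 2 - a[None, :] + beta[None, :] * (xbar[None, :] - bv) ** 2


def update_memberships(x: np.ndarray, xbar: np.ndarray, v: np.ndarray,
                       b: np.ndarray, a: np.ndarray, beta: np.ndarray,
                       cfg: FCMConfig) -> np.ndarray:
    """Closed-form membership update (inverse-power of the aggregated
    distance, normalized over clusters).

    Pixels with an exactly zero distance to one or more centers get a crisp
    assignment split equally among those centers; negative aggregated
    distances (possible when a_k > 0) are clipped at a small epsilon.
    """
    d = _aggregated_distance(x, xbar, v, b, a, beta)
    if (d < 0).any():
        logger.warning("negative aggregated distances clipped at %g "
                       "(a_k exceeds the data terms for %d pixel-cluster pairs)",
                       _EPS, int((d < 0).sum()))
    zero = d < _EPS
    d = np.maximum(d, _EPS)
    powered = d ** (-1.0 / (cfg.m - 1.0))
    u = powered / powered.sum(axis=0, keepdims=True)
    hit = zero.any(axis=0)
    if hit.any():
        crisp = zero[:, hit] / zero[:, hit].sum(axis=0, keepdims=True)
        u[:, hit] = crisp
    return u


def update_centers(x: np.ndarray, xbar: np.ndarray, u: np.ndarray,
                   b: np.ndarray, beta: np.ndarray, cfg: FCMConfig) -> np.ndarray:
    """Closed-form center update: bias- and membership-weighted mean of
    ``x_k + beta_k xbar_k`` normalized by ``b_k^2 (1 + beta_k)`` terms.

    An empty cluster (vanishing denominator) is re-seeded at the pixel with
    the lowest maximum membership.
    """
    um = u ** cfg.m
    num = um @ (b * (x + beta * xbar))
    den = um @ (b**2 * (1.0 + beta))
    v = np.empty(cfg.c)
    for i in range(cfg.c):
        if den[i] <= _EPS:
            k = int(np.argmin(u.max(axis=0)))
            v[i] = x[k]
            logger.warning("re-seeded empty cluster %d at pixel %d", i, k)
        else:
            v[i] = num[i] / den[i]
    return v


def objective(x: np.ndarray, xbar: np.ndarray, u: np.ndarray, v: np.ndarray,
              b_raster: np.ndarray, a: np.ndarray, beta: np.ndarray,
              cfg: FCMConfig, shape: tuple[int, int]) -> float:
    """Evaluate J_m with the bias ``b(r)`` taken at the window positions.

    The kernel-weighted window sums are computed exactly via the moment
    rasters ``B1 = K * b`` and ``B2 = K * b^2`` (circular correlation), so
    the value reduces to the collapsed form when the bias is constant.
    """
    kern = spatial_kernel(cfg.window_radius)
    b_img = b_raster.reshape(shape)
    b1 = _kernel_correlate(b_img, kern).ravel()
    b2 = _kernel_correlate(b_img**2, kern).ravel()
    um = u ** cfg.m
    vv = v[:, None]
    local = x[None, :] ** 2 - 2.0 * x[None, :] * vv * b1[None, :] + vv**2 * b2[None, :]
    nonlocal_ = xbar[None, :] ** 2 - 2.0 * xbar[None, :] * vv * b1[None, :] + vv**2 * b2[None, :]
    j_local = float((um * local).sum())
    j_nl = float((um * beta[None, :] * nonlocal_).sum())
    j_a = float((a[None, :] * um * (1.0 - u ** (cfg.m - 1.0))).sum())
    return j_local + j_nl + j_a


def _kernel_correlate(img: np.ndarray, kern: np.ndarray) -> np.ndarray:
    radius = kern.shape[0] // 2
    out = np.zeros_like(img, dtype=float)
    for dr in range(-radius, radius + 1):
        for dc in range(-radius, radius + 1):
            out += kern[dr + radius, dc + radius] * np.roll(img, (-dr, -dc), axis=(0, 1))
    return out


def _init_centers(x: np.ndarray, cfg: FCMConfig) -> np.ndarray:
    """Centers at evenly spaced intensity quantiles with tiny seeded jitter."""
    rng = np.random.default_rng(cfg.seed)
    qs = (np.arange(cfg.c) + 0.5) / cfg.c
    v = np.quantile(x, qs)
    span = float(x.max() - x.min()) or 1.0
    v = v + rng.uniform(-1e-3, 1e-3, size=cfg.c) * span
    return np.sort(v)


def segment(img: np.ndarray, cfg: FCMConfig | None = None,
            bias: np.ndarray | None = None,
            levels: int = 256) -> tuple[FCMState, np.ndarray]:
    """Run the full alternating optimization on a gray image.

    Returns the final state and the label raster (argmax membership);
    deterministic given ``cfg.seed``.
    """
    cfg = cfg or FCMConfig()
    arr = validate_gray_image(img, levels=levels).astype(float)
    shape = arr.shape
    x = arr.ravel()
    a, beta, xbar = compute_weights(arr, cfg)
    b = np.ones_like(x) if bias is None else np.asarray(bias, dtype=float).ravel()
    if b.shape != x.shape:
        raise ValueError("bias raster shape must match the image")
    v = _init_centers(x, cfg)
    u = update_memberships(x, xbar, v, b, a, beta, cfg)
    state = FCMState(u=u, v=v, b=b, xbar=xbar, a=a, beta=beta)
    for it in range(1, cfg.max_iter + 1):
        v = update_centers(x, xbar, u, b, beta, cfg)
        state.objective_trace.append(objective(x, xbar, u, v, b, a, beta, cfg, shape))
        u_new = update_memberships(x, xbar, v, b, a, beta, cfg)
        delta = float(np.abs(u_new - u).max())
        u = u_new
        state.n_iter = it
        if delta < cfg.tol:
            state.converged = True
            break
    state.u = u
    state.v = v
    labels = np.argmax(u, axis=0).reshape(shape)
    return state, labels
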