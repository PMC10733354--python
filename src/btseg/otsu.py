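"""Global thresholding by maximization of between-class variance.

The gray-level histogram is treated as a probability mass function
``p_i = n_i / N`` over levels ``0 .. L-1``.  For a candidate threshold ``k``
the background class is ``{0..k}`` and the foreground ``{k+1..L-1}``; the
class probabilities, means and variances decompose the total variance into
within-class and between-class parts,

    sigma^2 = sigma_w^2(k) + sigma_b^2(k),

and the selected threshold maximizes ``sigma_b^2``.  The binary mask then
uses the rule ``g = 1 iff f >= T`` with ``T = k* + 1``, so that levels up to
and including ``k*`` form the background.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .imgio import validate_gray_image

__all__ = [
    "Histogram",
    "OtsuState",
    "compute_histogram",
    "class_statistics",
    "otsu_threshold",
    "between_class_variance_profile",
    "binarize",
]


@dataclass(frozen=True)
class Histogram:
    """Gray-level counts and probabilities of an image."""

    counts: np.ndarray   # n_i, per-level pixel counts, length L
    probs: np.ndarray    # p_i = n_i / N
    n_pixels: int        # N
    levels: int          # L

    def __post_init__(self) -> None:
        if len(self.counts) != self.levels or len(self.probs) != self.levels:
            raise ValueError("histogram length must equal the level count")
        if self.n_pixels <= 0:
            raise ValueError("empty histogram")


@dataclass(frozen=True)
class OtsuState:
    """Class moments of the background/foreground split at threshold k.

    Background = levels 0..k, foreground = levels k+1..L-1.  Empty classes
    carry probability 0 with mean and variance defined as 0.
    """

    k: int
    s_x: float         # background class probability
    s_y: float         # foreground class probability
    mu_x: float        # background mean gray level
    mu_y: float        # foreground mean gray level
    mu: float          # global mean
    var_x: float       # background variance
    var_y: float       # foreground variance
    var_total: float   # global variance
    var_within: float  # s_x var_x + s_y var_y
    var_between: float  # s_x (mu_x - mu)^2 + s_y (mu_y - mu)^2


def compute_histogram(img: np.ndarray, levels: int = 256) -> Histogram:
    """Per-level pixel counts and the normalized probability mass function."""
    arr = validate_gray_image(img, levels=levels)
    counts = np.bincount(arr.ravel().astype(np.int64), minlength=levels)
    n = int(counts.sum())
    return Histogram(counts=counts, probs=counts / n, n_pixels=n, levels=levels)


def _class_moments(p: np.ndarray, idx: np.ndarray) -> tuple[float, float, float]:
    """(probability, mean, variance) of the class on levels *idx*."""
    s = float(p[idx].sum())
    if s <= 0.0:
        return 0.0, 0.0, 0.0
    mu = float((idx * p[idx]).sum() / s)
    var = float(((idx - mu) ** 2 * p[idx]).sum() / s)
    return s, mu, var


def class_statistics(hist: Histogram, k: int) -> OtsuState:
    """All class moments of the split at threshold level *k*."""
    L = hist.levels
    if not 0 <= k <= L - 2:
        raise ValueError(f"k must lie in [0, {L - 2}], got {k}")
    p = hist.probs
    levels = np.arange(L)
    s_x, mu_x, var_x = _class_moments(p, levels[: k + 1])
    s_y, mu_y, var_y = _class_moments(p, levels[k + 1:])
    mu = float((levels * p).sum())
    var_total = float(((levels - mu) ** 2 * p).sum())
    var_within = s_x * var_x + s_y * var_y
    var_between = s_x * (mu_x - mu) ** 2 + s_y * (mu_y - mu) ** 2
    return OtsuState(k=k, s_x=s_x, s_y=s_y, mu_x=mu_x, mu_y=mu_y, mu=mu,
                     var_x=var_x, var_y=var_y, var_total=var_total,
                     var_within=var_within, var_between=var_between)


def between_class_variance_profile(hist: Histogram) -> np.ndarray:
    """sigma_b^2(k) for every k in [0, L-2], computed from cumulative moments."""
    p = hist.probs
    levels = np.arange(hist.levels)
    w = np.cumsum(p)[:-1]                 # s_x(k)
    m = np.cumsum(levels * p)[:-1]        # first moment up to k
    mu = float((levels * p).sum())
    num = (mu * w - m) ** 2
    den = w * (1.0 - w)
    with np.errstate(divide="ignore", invalid="ignore"):
        sigma_b2 = np.where(den > 0, num / den, 0.0)
    return sigma_b2


def otsu_threshold(hist: Histogram) -> int:
    """The smallest k in [0, L-2] maximizing the between-class variance.

    The maximization runs in exact integer arithmetic on the raw counts
    (sigma_b^2(k) is proportional to the rational (N M_k - M W_k)^2 /
    (W_k (N - W_k))), so ties are resolved deterministically to the smallest
    k with no floating-point ambiguity.  Raises on a degenerate
    (single-level) histogram, for which every split has zero between-class
    variance.
    """
    if np.count_nonzero(hist.counts) < 2:
        raise ValueError("histogram has fewer than 2 non-empty levels")
    counts = [int(c) for c in hist.counts]
    n_total = sum(counts)
    m_total = sum(i * c for i, c in enumerate(counts))
    best_k, best_num, best_den = 0, -1, 1
    w = m = 0
    for k in range(hist.levels - 1):
        w += counts[k]
        m += k * counts[k]
        den = w * (n_total - w)
        if den == 0:
            continue
        num = (m_total * w - n_total * m) ** 2
        if num * best_den > best_num * den:  # exact fraction comparison
            best_k, best_num, best_den = k, num, den
    return best_k


def binarize(img: np.ndarray, threshold: int, levels: int = 256) -> np.ndarray:
    """Binary mask with 1 where intensity >= threshold, else 0."""
    arr = validate_gray_image(img, levels=levels)
    if not 0 <= threshold <= levels - 1:
        raise ValueError(f"threshold must lie in [0, {levels - 1}]")
    return arr >= threshold
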