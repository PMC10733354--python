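"""Confusion-matrix scores and the Dice similarity coefficient.

Conventions for degenerate inputs: a 0/0 ratio (e.g. precision with no
positive predictions) is reported as 0.0 with ``degenerate=True`` on the
score set; the Dice coefficient of two empty masks is defined as 1.0, also
flagged.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["ConfusionCounts", "ScoreSet", "confusion", "scores", "f_from_pr", "dice"]


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(self.tp + other.tp, self.tn + other.tn,
                               self.fp + other.fp, self.fn + other.fn)


@dataclass(frozen=True)
class ScoreSet:
    recall: float
    precision: float
    f_measure: float
    accuracy: float
    dice: float | None = None
    degenerate: bool = field(default=False, compare=False)


def confusion(y_true, y_pred, positive) -> ConfusionCounts:
    """Count tp/tn/fp/fn with *positive* as the positive label."""
    t = np.asarray(y_true)
    p = np.asarray(y_pred)
    if t.shape != p.shape or t.size == 0:
        raise ValueError("label vectors must be non-empty and of equal length")
    pos_t = t == positive
    pos_p = p == positive
    return ConfusionCounts(
        tp=int(np.sum(pos_t & pos_p)),
        tn=int(np.sum(~pos_t & ~pos_p)),
        fp=int(np.sum(~pos_t & pos_p)),
        fn=int(np.sum(pos_t & ~pos_p)),
    )


def scores(cm: ConfusionCounts) -> ScoreSet:
    """recall, precision, F-measure and accuracy from confusion counts."""
    if cm.total == 0:
        raise ValueError("cannot score an empty confusion matrix")
    degenerate = False
    if cm.tp + cm.fn > 0:
        recall = cm.tp / (cm.tp + cm.fn)
    else:
        recall, degenerate = 0.0, True
    if cm.tp + cm.fp > 0:
        precision = cm.tp / (cm.tp + cm.fp)
    else:
        precision, degenerate = 0.0, True
    f, f_degen = _harmonic(precision, recall)
    return ScoreSet(recall=recall, precision=precision, f_measure=f,
                    accuracy=(cm.tp + cm.tn) / cm.total,
                    degenerate=degenerate or f_degen)


def _harmonic(p: float, r: float) -> tuple[float, bool]:
    if p + r == 0.0:
        return 0.0, True
    return 2.0 * p * r / (p + r), False


def f_from_pr(precision: float, recall: float) -> float:
    """F-measure (harmonic mean) from precision and recall alone."""
    if not (0.0 <= precision <= 1.0 and 0.0 <= recall <= 1.0):
        raise ValueError("precision and recall must lie in [0, 1]")
    return _harmonic(precision, recall)[0]


def dice(a: np.ndarray, b: np.ndarray) -> float:
    """Dice similarity coefficient 2|A∩B| / (|A| + |B|) between two masks.

    Two empty masks are taken as perfectly overlapping (Dice 1.0).
    """
    a = np.asarray(a).astype(bool)
    b = np.asarray(b).astype(bool)
    if a.shape != b.shape:
        raise ValueError(f"mask shapes differ: {a.shape} vs {b.shape}")
    size = int(a.sum()) + int(b.sum())
    if size == 0:
        return 1.0
    return 2.0 * int(np.sum(a & b)) / size
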